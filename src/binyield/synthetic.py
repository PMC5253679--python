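"""Synthetic inputs with known structure: weather, regions and yield panels.

Everything downstream (exposure computation, panel estimation, comparison,
decomposition) is exercised on data generated here.  Two yield generators
are provided: a *statistical* one that runs the panel regression equation
generatively with known coefficients and spatially correlated errors (so
estimates can be checked against the truth), and a *mechanistic* soil-water
bucket surrogate in which heat damages yield only through crop water stress
(evaporative demand rises with temperature; supply is limited by a bucket
refilled by rain), reproducing the rainfed-vs-irrigated response contrast.

All generators are pure functions of their configuration, including the
seed: identical configurations give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .bins import BinScheme
from .regions import RegionMap
from .seasons import GrowingSeason
from .weather import DailyWeatherGrid
from .exposure import ExposurePanel, years_available

__all__ = [
    "ClimateGenConfig",
    "RegionGenConfig",
    "TrueModel",
    "SurrogateCropParams",
    "gen_weather",
    "gen_regions",
    "gen_yields_statistical",
    "gen_yields_surrogate",
    "default_true_model",
]


@dataclass(frozen=True)
class ClimateGenConfig:
    """Configuration of the gridded daily weather generator.

    Daily mean temperature per cell is a seasonal sinusoid around
    ``base_mean_temp`` (plus a small latitudinal gradient) with an AR(1)
    anomaly split between a region-wide and a cell-specific component, plus
    ``warming_offset`` (degC, uniform; use for "future" scenarios).  Tmin and
    Tmax straddle the mean by half a lognormally distributed diurnal range.
    Precipitation is a wet-day Bernoulli with gamma-distributed amounts.
    """

    grid_rows: int = 8
    grid_cols: int = 8
    years: int = 31
    start_year: int = 1980
    base_mean_temp: float = 11.0          # degC, annual mean at the grid origin
    seasonal_amplitude: float = 14.0      # degC, half peak-to-trough of the annual cycle
    diurnal_range_mean: float = 11.0      # degC
    anomaly_sd: float = 3.5               # degC, stationary sd of the AR(1) anomaly
    anomaly_ar1: float = 0.70
    warming_offset: float = 0.0           # degC added uniformly
    precip_shape: float = 0.8             # gamma shape of wet-day rain
    precip_scale: float = 8.0             # gamma scale, mm
    wet_day_prob: float = 0.35
    lat0: float = 36.0                    # grid origin, degrees
    lon0: float = -100.0
    cell_spacing: float = 0.5             # degrees between neighbouring cells
    lat_gradient: float = -0.6            # degC per degree latitude northwards
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.years <= 0:
            raise ValueError("years must be positive")
        if self.diurnal_range_mean <= 0:
            raise ValueError("diurnal_range_mean must be positive")
        if not 0 <= self.anomaly_ar1 < 1:
            raise ValueError("anomaly_ar1 must lie in [0, 1)")
        if not 0 <= self.wet_day_prob <= 1:
            raise ValueError("wet_day_prob must lie in [0, 1]")


def gen_weather(cfg: ClimateGenConfig) -> DailyWeatherGrid:
    """Generate the daily Tmin/Tmax/precip grid described by ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    n_cells = cfg.grid_rows * cfg.grid_cols
    rows, cols = np.divmod(np.arange(n_cells), cfg.grid_cols)
    lat = cfg.lat0 + cfg.cell_spacing * rows
    lon = cfg.lon0 + cfg.cell_spacing * cols

    times = pd.date_range(
        f"{cfg.start_year}-01-01", f"{cfg.start_year + cfg.years - 1}-12-31", freq="D"
    )
    n_days = len(times)
    doy = times.dayofyear.to_numpy()
    # annual cycle: coldest mid-January, warmest mid-July
    seasonal = -cfg.seasonal_amplitude * np.cos(2 * np.pi * (doy - 15) / 365.25)

    # AR(1) anomalies: equal-variance regional + cell-specific components
    rho = cfg.anomaly_ar1
    innov_sd = cfg.anomaly_sd * np.sqrt(1 - rho**2)
    shocks = rng.normal(0.0, innov_sd, size=(n_days, n_cells + 1))
    anom = np.empty_like(shocks)
    anom[0] = shocks[0] / np.sqrt(1 - rho**2)
    for t in range(1, n_days):
        anom[t] = rho * anom[t - 1] + shocks[t]
    regional, cellwise = anom[:, 0], anom[:, 1:]
    anomaly = np.sqrt(0.5) * regional[:, None] + np.sqrt(0.5) * cellwise

    tmean = (
        cfg.base_mean_temp
        + cfg.lat_gradient * (lat - cfg.lat0)[None, :]
        + seasonal[:, None]
        + anomaly
        + cfg.warming_offset
    )
    # lognormal diurnal range with mean diurnal_range_mean
    sig = 0.2
    diurnal = cfg.diurnal_range_mean * np.exp(
        rng.normal(0.0, sig, size=(n_days, n_cells)) - sig**2 / 2
    )
    wet = rng.random((n_days, n_cells)) < cfg.wet_day_prob
    amounts = rng.gamma(cfg.precip_shape, cfg.precip_scale, size=(n_days, n_cells))
    precip = np.where(wet, amounts, 0.0)

    ds = xr.Dataset(
        {
            "tmin": (("time", "cell"), tmean - diurnal / 2),
            "tmax": (("time", "cell"), tmean + diurnal / 2),
            "precip": (("time", "cell"), precip),
        },
        coords={
            "time": times,
            "cell": np.arange(n_cells),
            "lat": ("cell", lat),
            "lon": ("cell", lon),
        },
    )
    return DailyWeatherGrid(ds)


@dataclass(frozen=True)
class RegionGenConfig:
    """Configuration of the cells -> counties -> states partition.

    ``rainfed_share_dist`` describes the county rainfed crop-area share:
    ``("beta", a, b)`` or ``("mixture", p, (a1, b1), (a2, b2))`` drawing from
    Beta(a1, b1) with probability p, else Beta(a2, b2).  The default mixture
    gives mostly strongly rainfed counties plus a minority of strongly
    irrigated ones, so both regimes survive the share-threshold
    classification.
    """

    n_counties: int = 16
    cells_per_county: int = 4
    n_states: int = 4
    rainfed_share_dist: tuple = ("mixture", 0.75, (12.0, 1.0), (1.0, 12.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_counties >= self.n_states >= 1:
            raise ValueError("need n_counties >= n_states >= 1")
        if self.cells_per_county < 1:
            raise ValueError("cells_per_county must be >= 1")


def _draw_shares(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "beta":
        return rng.beta(dist[1], dist[2], size=n)
    if kind == "mixture":
        _, p, (a1, b1), (a2, b2) = dist
        pick = rng.random(n) < p
        return np.where(pick, rng.beta(a1, b1, size=n), rng.beta(a2, b2, size=n))
    raise ValueError(f"unknown rainfed_share_dist kind {kind!r}")


def gen_regions(cfg: RegionGenConfig, grid: DailyWeatherGrid) -> RegionMap:
    """Partition the weather grid's cells into weighted counties and states.

    Counties take consecutive row-major blocks of cells (spatially coherent
    on the grid); counties are grouped into near-equal-sized states.  Cell
    crop-area weights are Dirichlet-distributed within each county.
    """
    cells = grid.cells
    need = cfg.n_counties * cfg.cells_per_county
    if len(cells) < need:
        raise ValueError(
            f"grid has {len(cells)} cells; {need} needed for "
            f"{cfg.n_counties} counties x {cfg.cells_per_county} cells"
        )
    rng = np.random.default_rng(cfg.seed)
    used = cells[:need]
    county_of_cell = np.repeat(np.arange(cfg.n_counties), cfg.cells_per_county)
    weights = rng.dirichlet(np.full(cfg.cells_per_county, 2.0), size=cfg.n_counties).ravel()
    lat = grid.lat.loc[used].to_numpy()
    lon = grid.lon.loc[used].to_numpy()
    cells_df = pd.DataFrame(
        {
            "cell_id": used,
            "lat": lat,
            "lon": lon,
            "county_id": county_of_cell,
            "weight": weights,
        }
    )
    state_of_county = (np.arange(cfg.n_counties) * cfg.n_states) // cfg.n_counties
    counties_df = pd.DataFrame(
        {
            "county_id": np.arange(cfg.n_counties),
            "state_id": state_of_county,
            "rainfed_share": _draw_shares(cfg.rainfed_share_dist, cfg.n_counties, rng),
        }
    )
    return RegionMap(cells_df, counties_df)


# realistic inverted-U bin response: mildly beneficial warmth up to ~27 degC,
# sharply detrimental above 30 degC (per day of exposure, log scale)
_DEFAULT_GAMMA = {
    "bin_0_3": 0.0000,
    "bin_3_6": 0.0002,
    "bin_6_9": 0.0008,
    "bin_9_12": 0.0015,
    "bin_12_15": 0.0025,
    "bin_15_18": 0.0035,
    "bin_18_21": 0.0045,
    "bin_21_24": 0.0055,
    "bin_24_27": 0.0060,
    "bin_27_30": 0.0030,
    "bin_30_33": -0.0060,
    "bin_33_36": -0.0400,
    "bin_36_39": -0.0600,
    "bin_39_42": -0.0800,
}


@dataclass(frozen=True)
class TrueModel:
    """Known data-generating parameters of the statistical yield generator.

    Mirrors the regression: common intercept, county effects, per-bin
    exposure coefficients, precipitation terms, state time trends, and a
    Gaussian residual field with exponential spatial covariance
    ``exp(-d / error_spatial_range)`` across county centroids (independent
    across years; iid across counties when the range is zero).
    """

    gamma: dict = field(default_factory=lambda: dict(_DEFAULT_GAMMA))
    delta_precip_lin: float = 8e-4        # log yield per mm
    delta_precip_quad: float = -8e-7      # log yield per mm^2
    alpha0: float = 1.8                   # log(t/ha)
    county_effects: dict = field(default_factory=dict)
    state_trend_lin: dict = field(default_factory=dict)   # per year
    state_trend_quad: dict = field(default_factory=dict)  # per year^2
    error_sd: float = 0.10                # log-yield units
    error_spatial_range: float = 0.5      # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.error_sd < 0:
            raise ValueError("error_sd must be nonnegative")
        if self.error_spatial_range < 0:
            raise ValueError("error_spatial_range must be nonnegative")


def default_true_model(regions: RegionMap, seed: int = 0, **overrides) -> TrueModel:
    """A TrueModel with county effects and state trends drawn for ``regions``."""
    rng = np.random.default_rng(seed)
    counties = regions.county_ids
    states = np.unique(regions.counties["state_id"])
    fields = dict(
        county_effects={int(c): float(v) for c, v in zip(counties, rng.normal(0, 0.20, len(counties)))},
        state_trend_lin={int(s): float(v) for s, v in zip(states, rng.normal(0.01, 0.004, len(states)))},
        state_trend_quad={int(s): float(v) for s, v in zip(states, rng.normal(0, 2e-4, len(states)))},
        seed=seed,
    )
    fields.update(overrides)
    return TrueModel(**fields)


def gen_yields_statistical(
    exposures: ExposurePanel,
    truth: TrueModel,
    regions: RegionMap,
    source: str = "statistical-truth",
    scenario: str = "historical",
) -> pd.DataFrame:
    """Yield panel drawn exactly from the regression equation.

    log yield = alpha0 + c_i + sum_h gamma_h x_ith + delta * (P, P^2)
    + state trends (centered year, matching the estimator's convention)
    + spatially correlated Gaussian error, independent across years.
    """
    bins = exposures.bin_labels
    missing = [b for b in bins if b not in truth.gamma]
    if missing or len(truth.gamma) != len(bins):
        raise ValueError(
            f"truth.gamma bins do not match the exposure scheme (missing {missing}, "
            f"{len(truth.gamma)} given vs {len(bins)} expected)"
        )
    df = exposures.frame.copy()
    states = regions.states()
    df["state_id"] = df["county_id"].map(states)
    if df["state_id"].isna().any():
        raise ValueError("exposure counties missing from the region map")

    gvec = np.array([truth.gamma[b] for b in bins])
    logy = (
        truth.alpha0
        + df[list(bins)].to_numpy() @ gvec
        + truth.delta_precip_lin * df["season_precip"].to_numpy()
        + truth.delta_precip_quad * df["season_precip"].to_numpy() ** 2
    )
    logy += df["county_id"].map(lambda c: truth.county_effects.get(int(c), 0.0)).to_numpy()
    t = df["year"].to_numpy(float) - df["year"].mean()
    lin = df["state_id"].map(lambda s: truth.state_trend_lin.get(int(s), 0.0)).to_numpy()
    quad = df["state_id"].map(lambda s: truth.state_trend_quad.get(int(s), 0.0)).to_numpy()
    logy += lin * t + quad * t**2

    if truth.error_sd > 0:
        rng = np.random.default_rng(truth.seed)
        counties = np.sort(df["county_id"].unique())
        cent = regions.centroids().loc[counties].to_numpy(float)
        diff = cent[:, None, :] - cent[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        if truth.error_spatial_range > 0:
            cov = truth.error_sd**2 * np.exp(-dist / truth.error_spatial_range)
            chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(counties)))
        else:
            chol = truth.error_sd * np.eye(len(counties))
        years = np.sort(df["year"].unique())
        draws = pd.DataFrame(
            (chol @ rng.standard_normal((len(counties), len(years)))).T,
            index=years,
            columns=counties,
        )
        logy += draws.stack().reindex(
            pd.MultiIndex.from_arrays([df["year"], df["county_id"]])
        ).to_numpy()

    out = df[["county_id", "year"]].copy()
    out["state_id"] = df["state_id"]
    out["yield"] = np.exp(logy)
    out["source"] = source
    out["scenario"] = scenario
    out["regime"] = exposures.regime or "rainfed"
    return out[["county_id", "state_id", "year", "yield", "source", "scenario", "regime"]]


@dataclass(frozen=True)
class SurrogateCropParams:
    """Parameters of the soil-water-bucket crop surrogate.

    Daily evaporative demand rises linearly with mean temperature above
    ``et_ref_temp``; supply is capped by the current bucket content; the
    bucket gains rain and loses supply, clipped to [0, capacity].  Yield
    falls linearly (on the log scale) with the seasonal mean stress
    1 - supply/demand.  Irrigated runs refill the bucket to capacity every
    day, which removes stress entirely.
    """

    bucket_capacity: float = 120.0        # mm, plant-available soil water
    initial_fill: float = 0.6             # fraction of capacity at season start
    et_base: float = 3.0                  # mm/day, demand at/below the reference temp
    et_temp_slope: float = 0.35           # mm/day per degC above reference
    et_ref_temp: float = 25.0             # degC; places stress onset near 30 degC
    stress_yield_sensitivity: float = 2.0 # log-yield per unit seasonal mean stress
    potential_log_yield: float = 2.30     # log(t/ha), ~10 t/ha unstressed
    irrigated: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bucket_capacity <= 0:
            raise ValueError("bucket_capacity must be positive")
        if not 0 <= self.initial_fill <= 1:
            raise ValueError("initial_fill must lie in [0, 1]")
        if self.et_temp_slope < 0:
            raise ValueError("et_temp_slope must be nonnegative")


def gen_yields_surrogate(
    weather: DailyWeatherGrid,
    regions: RegionMap,
    params: SurrogateCropParams,
    season: GrowingSeason,
    years=None,
    source: str = "surrogate",
    scenario: str = "historical",
) -> pd.DataFrame:
    """Yield panel from the mechanistic water-stress surrogate.

    Per cell and season day: demand = et_base + slope * max(0, Tmean - ref);
    supply = min(bucket, demand); bucket += precip - supply (clipped);
    irrigated runs reset the bucket to capacity daily.  Cell log yield is
    potential minus sensitivity times the seasonal mean stress
    (1 - supply/demand); county yields aggregate cells with the same
    crop-area weights as the exposures.
    """
    if years is None:
        years = years_available(weather, season)
    if not list(years):
        raise ValueError("no harvest year with complete season coverage")
    regime = "irrigated" if params.irrigated else "rainfed"
    w = regions.cell_weights(regime)
    states = regions.states()

    rows = []
    for year in years:
        start, end = season.window(int(year))
        ds = weather.window(start, end)
        tmean = (ds["tmin"].values + ds["tmax"].values) / 2.0  # (day, cell)
        precip = ds["precip"].values
        n_days, n_cells = tmean.shape
        bucket = np.full(n_cells, params.initial_fill * params.bucket_capacity)
        stress_sum = np.zeros(n_cells)
        for day in range(n_days):
            if params.irrigated:
                bucket[:] = params.bucket_capacity
            demand = params.et_base + params.et_temp_slope * np.clip(
                tmean[day] - params.et_ref_temp, 0.0, None
            )
            supply = np.minimum(bucket, demand)
            with np.errstate(invalid="ignore", divide="ignore"):
                stress = np.where(demand > 0, 1.0 - supply / np.where(demand > 0, demand, 1.0), 0.0)
            stress_sum += stress
            bucket = np.clip(bucket + precip[day] - supply, 0.0, params.bucket_capacity)
        log_yield_cell = (
            params.potential_log_yield
            - params.stress_yield_sensitivity * stress_sum / n_days
        )
        cell_logy = pd.Series(log_yield_cell, index=weather.cells)
        wy = w.assign(logy=cell_logy.loc[w["cell_id"]].to_numpy())
        county_logy = (
            wy.assign(wl=wy["weight"] * wy["logy"]).groupby("county_id")["wl"].sum()
        )
        for county, ly in county_logy.items():
            rows.append(
                {
                    "county_id": county,
                    "state_id": states[county],
                    "year": int(year),
                    "yield": float(np.exp(ly)),
                    "source": source,
                    "scenario": scenario,
                    "regime": regime,
                }
            )
    return pd.DataFrame(rows)
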