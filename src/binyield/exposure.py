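"""Growing-season temperature-bin exposure, cell level and county level.

For every cell-day the sinusoidal interpolation gives the time spent in each
fine 1 degC bin; summing over the growing season and pooling to 3 K bins
yields the exposure covariates of the yield regression.  County records are
crop-area-weighted means over member cells.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .bins import BinScheme, fraction_above
from .regions import RegionMap
from .seasons import GrowingSeason
from .weather import DailyWeatherGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ExposurePanel",
    "season_exposure",
    "aggregate_to_counties",
    "years_available",
]

META_COLS = ("season_precip", "season_length", "time_below_0")


class ExposurePanel:
    """Per-unit (cell or county) per-year exposure covariates.

    Columns: the unit key (``cell_id`` or ``county_id``), ``year`` (harvest
    year), one column per pooled 3 K bin (``bin_0_3`` ... ``bin_39_42``, in
    days), fine 1 degC bin columns (``fbin_12_13`` ...) used for degree-day
    covariates, ``time_below_0`` (days below the lower limit, excluded from
    covariates), ``season_precip`` (mm) and ``season_length`` (days).
    """

    def __init__(self, frame: pd.DataFrame, scheme: BinScheme, regime: str | None = None):
        self.scheme = scheme
        self.regime = regime
        key = "county_id" if "county_id" in frame.columns else "cell_id"
        for col in (key, "year", "season_precip", "season_length"):
            if col not in frame.columns:
                raise ValueError(f"exposure table missing column {col!r}")
        missing = [b for b in scheme.pooled_labels if b not in frame.columns]
        if missing:
            raise ValueError(f"exposure table missing bin columns: {missing}")
        if frame.duplicated([key, "year"]).any():
            raise ValueError("duplicate unit-year rows in exposure table")
        self.key = key
        self.frame = frame.reset_index(drop=True)

    @property
    def bin_labels(self) -> list[str]:
        return self.scheme.pooled_labels

    @property
    def fine_labels(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("fbin_")]

    def check_conservation(self, atol: float = 1e-9) -> None:
        """Pooled bins + below-limit time must account for every season day."""
        total = self.frame[list(self.bin_labels)].sum(axis=1)
        if "time_below_0" in self.frame.columns:
            total = total + self.frame["time_below_0"]
        err = (total - self.frame["season_length"]).abs().max()
        if err > atol:
            raise AssertionError(f"bin times do not sum to season length (max err {err:g})")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scheme: BinScheme | None = None, regime: str | None = None):
        return cls(pd.read_csv(path), scheme or BinScheme(), regime)

    def __repr__(self) -> str:
        return (
            f"<ExposurePanel {self.key} x year: {len(self.frame)} rows, "
            f"{len(self.bin_labels)} pooled bins, regime={self.regime}>"
        )


def years_available(grid: DailyWeatherGrid, season: GrowingSeason) -> list[int]:
    """Harvest years whose full season window lies inside the weather record."""
    t0, t1 = grid.times[0], grid.times[-1]
    years = []
    for y in range(t0.year, t1.year + 1):
        start, end = season.window(y)
        if pd.Timestamp(start) >= t0 and pd.Timestamp(end) <= t1:
            years.append(y)
    return years


def _season_exposure_one_year(
    grid: DailyWeatherGrid, season: GrowingSeason, year: int, scheme: BinScheme
) -> pd.DataFrame:
    start, end = season.window(year)
    ds = grid.window(start, end)
    n_days = ds.sizes["time"]
    expected = season.length(year)
    if n_days != expected:
        raise ValueError(
            f"season {season.crop} {year}: {n_days} days present, {expected} expected"
        )
    tmin = ds["tmin"].values  # (time, cell)
    tmax = ds["tmax"].values
    edges = scheme.fine_edges
    # season total time above each edge, per cell: sum over days commutes
    # with the CDF differencing, so fine-bin season sums come from edge sums
    sum_fa = np.empty((tmin.shape[1], edges.size))
    for j, e in enumerate(edges):
        sum_fa[:, j] = fraction_above(tmin, tmax, e).sum(axis=0)
    below = n_days - sum_fa[:, 0]
    fine = sum_fa[:, :-1] - sum_fa[:, 1:]
    top = sum_fa[:, -1]

    per_pool = int(round(scheme.pooled_width / scheme.fine_width))
    n_pool = scheme.n_pooled - 1
    pooled = fine.reshape(fine.shape[0], n_pool, per_pool).sum(axis=2)

    out = pd.DataFrame({"cell_id": grid.cells, "year": year})
    for k, lab in enumerate(scheme.pooled_labels[:-1]):
        out[lab] = pooled[:, k]
    out[scheme.pooled_labels[-1]] = top
    fe = edges
    for k in range(fine.shape[1]):
        out[f"fbin_{_flab(fe[k])}_{_flab(fe[k + 1])}"] = fine[:, k]
    out["time_below_0"] = below
    out["season_precip"] = ds["precip"].values.sum(axis=0)
    out["season_length"] = float(n_days)
    return out


def _flab(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x).replace(".", "p")


def season_exposure(
    grid: DailyWeatherGrid,
    season: GrowingSeason,
    years=None,
    scheme: BinScheme | None = None,
) -> ExposurePanel:
    """Per-cell exposure records for the given harvest years.

    ``years=None`` uses every harvest year fully covered by the record.
    Missing season days raise; there is no silent gap-filling.
    """
    scheme = scheme or BinScheme()
    if years is None:
        years = years_available(grid, season)
    if not list(years):
        raise ValueError("no harvest year with complete season coverage")
    frames = [_season_exposure_one_year(grid, season, int(y), scheme) for y in years]
    return ExposurePanel(pd.concat(frames, ignore_index=True), scheme)


def aggregate_to_counties(
    cell_exposures: ExposurePanel, regions: RegionMap, regime: str = "rainfed"
) -> ExposurePanel:
    """Crop-area-weighted county exposure records.

    County exposure = sum over member cells of (within-county renormalized
    weight) x cell exposure, applied alike to bin times and precipitation.
    Counties with zero total weight for the regime were already dropped by
    :meth:`RegionMap.cell_weights` (with a warning).
    """
    w = regions.cell_weights(regime)
    df = cell_exposures.frame.merge(w, on="cell_id", how="inner")
    lost = set(w["cell_id"]) - set(cell_exposures.frame["cell_id"])
    if lost:
        raise ValueError(f"cells missing from exposure table: {sorted(lost)[:10]}")
    value_cols = [
        c
        for c in cell_exposures.frame.columns
        if c not in ("cell_id", "year") and pd.api.types.is_numeric_dtype(df[c])
    ]
    weighted = df[value_cols].multiply(df["weight"], axis=0)
    weighted[["county_id", "year"]] = df[["county_id", "year"]]
    out = weighted.groupby(["county_id", "year"], as_index=False)[value_cols].sum()
    dropped = regions.counties.shape[0] - out["county_id"].nunique()
    if dropped:
        logger.info("aggregated to %d counties (%d dropped)", out["county_id"].nunique(), dropped)
    return ExposurePanel(out, cell_exposures.scheme, regime)
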