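"""County fixed-effects panel regression of log yield on temperature exposure.

The model explains log county yield with the time spent in 3 K temperature
bins during the growing season,

    log Y_it = alpha_0 + c_i + sum_h gamma_h * x_ith + z_it' delta + eps_it,

where ``x_ith`` are days of exposure in bin h (step form) or a pair of
degree-day covariates around a knot (piecewise-linear form), ``c_i`` are
county fixed effects absorbed by the within transformation, and ``z_it``
holds season precipitation (linear + quadratic) and state-specific time
trends (linear + quadratic, centered year).  Time below 0 degC is excluded:
its effect is captured by the intercept/fixed effects.

Residuals may correlate across counties within a year; the covariance of the
estimates is therefore computed with a Conley-type spatial HAC sandwich with
a distance cutoff (default 3 degrees), collapsing to heteroskedasticity-
robust (HC0) when no two counties fall within the cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bins import BinScheme
from .exposure import ExposurePanel

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionSpec",
    "Design",
    "BinnedYieldModel",
    "BinnedYieldResults",
    "build_design",
    "conley_vcov",
    "ci_overlap_divergence",
    "ensemble_median",
]


@dataclass(frozen=True)
class RegressionSpec:
    """Configuration of the panel regression.

    response_form: ``step`` (one coefficient per pooled bin) or
        ``piecewise_linear`` (two degree-day covariates around ``knot``).
    knot: breakpoint in degC for the piecewise form.
    precip_terms: include season precipitation (linear + quadratic).
    trend_order: polynomial order of the state-specific time trends.
    ci_level: two-sided confidence level for intervals.
    spatial_cutoff: Conley distance cutoff in degrees.
    distance_metric: ``euclidean`` (degrees, default) or ``greatcircle`` (km,
        then the cutoff is in km).
    spatial_kernel: ``uniform`` (indicator, default) or ``bartlett``.
    """

    response_form: str = "step"
    scheme: BinScheme = field(default_factory=BinScheme)
    knot: float = 30.0
    precip_terms: bool = True
    trend_order: int = 2
    ci_level: float = 0.95
    spatial_cutoff: float = 3.0
    distance_metric: str = "euclidean"
    spatial_kernel: str = "uniform"

    def __post_init__(self) -> None:
        if self.response_form not in ("step", "piecewise_linear"):
            raise ValueError(f"unknown response_form {self.response_form!r}")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.spatial_cutoff < 0:
            raise ValueError("spatial_cutoff must be nonnegative")


@dataclass
class Design:
    """Assembled regression matrices for one panel."""

    y: pd.Series               # log yield
    X: pd.DataFrame            # slope covariates (no intercept, no county dummies)
    county: np.ndarray
    state: np.ndarray
    year: np.ndarray
    temp_cols: list[str]
    n_dropped: int

    @property
    def nobs(self) -> int:
        return len(self.y)


def _piecewise_cols(exposures: ExposurePanel, knot: float, scheme: BinScheme) -> pd.DataFrame:
    """Degree-day pair around the knot from fine-bin times at bin midpoints."""
    fine = exposures.fine_labels
    if not fine:
        raise ValueError("piecewise form needs fine-bin columns in the exposure table")
    mids = scheme.fine_midpoints  # fine midpoints + top-bin mean
    times = exposures.frame[fine + [scheme.pooled_labels[-1]]].to_numpy()
    lo = np.clip(mids, scheme.lower_limit, knot) - scheme.lower_limit
    hi = np.clip(mids - knot, 0.0, None)
    return pd.DataFrame(
        {"gdd_below_knot": times @ lo, "gdd_above_knot": times @ hi},
        index=exposures.frame.index,
    )


def build_design(
    exposures: ExposurePanel, yields: pd.DataFrame, spec: RegressionSpec | None = None
) -> Design:
    """Merge exposure and yield panels into regression matrices.

    ``yields`` needs columns ``county_id, state_id, year, yield``; rows with
    nonpositive or missing yield, or without a matching exposure record, are
    dropped with a logged count.
    """
    spec = spec or RegressionSpec()
    for col in ("county_id", "state_id", "year", "yield"):
        if col not in yields.columns:
            raise ValueError(f"yield panel missing column {col!r}")
    ok = yields["yield"].notna() & (yields["yield"] > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("dropping %d rows with missing/nonpositive yield", n_bad)
    yd = yields.loc[ok, ["county_id", "state_id", "year", "yield"]]
    if yd.duplicated(["county_id", "year"]).any():
        raise ValueError(
            "duplicate county-year rows in yield panel; fit one source at a time "
            "(use ensemble_median to collapse sources)"
        )
    merged = yd.merge(exposures.frame, on=["county_id", "year"], how="inner")
    n_unmatched = len(yd) - len(merged)
    if n_unmatched:
        logger.info("dropping %d yield rows without exposure records", n_unmatched)
    if merged.empty:
        raise ValueError("empty panel after merging yields with exposures")

    scheme = exposures.scheme
    sub = ExposurePanel(merged[[c for c in exposures.frame.columns]], scheme)
    if spec.response_form == "step":
        temp = merged[list(scheme.pooled_labels)].copy()
    else:
        temp = _piecewise_cols(sub, spec.knot, scheme)
    X = temp.copy()
    if spec.precip_terms:
        X["precip"] = merged["season_precip"]
        X["precip_sq"] = merged["season_precip"] ** 2
    year = merged["year"].to_numpy(int)
    t = year - year.mean()
    for s in np.unique(merged["state_id"]):
        m = (merged["state_id"] == s).to_numpy()
        for p in range(1, spec.trend_order + 1):
            X[f"trend{p}_{s}"] = np.where(m, t**p, 0.0)
    return Design(
        y=pd.Series(np.log(merged["yield"].to_numpy(float)), name="log_yield"),
        X=X.astype(float),
        county=merged["county_id"].to_numpy(),
        state=merged["state_id"].to_numpy(),
        year=year,
        temp_cols=list(temp.columns),
        n_dropped=n_bad + n_unmatched,
    )


def _demean_by(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    if values.ndim == 1:
        sums = np.bincount(codes, weights=values, minlength=n_groups)
        return values - (sums / counts)[codes]
    means = np.empty((n_groups, values.shape[1]))
    for j in range(values.shape[1]):
        means[:, j] = np.bincount(codes, weights=values[:, j], minlength=n_groups) / counts
    return values - means[codes]


class BinnedYieldModel:
    """Fixed-effects panel model of log yield on binned temperature exposure.

    Parameters
    ----------
    exposures : ExposurePanel
        County-by-year exposure covariates.
    yields : pandas.DataFrame
        Yield panel (``county_id, state_id, year, yield`` in t/ha; extra
        label columns such as ``source``/``scenario`` are carried through).
    spec : RegressionSpec, optional
    centroids : pandas.DataFrame, optional
        County centroids (``lat``/``lon``), indexed by ``county_id``;
        required for the Conley covariance.

    Examples
    --------
    >>> model = BinnedYieldModel(exposures, yields, centroids=regions.centroids())
    >>> res = model.fit()
    >>> res.gamma  # per-bin coefficients with spatial-HAC CIs
    """

    def __init__(
        self,
        exposures: ExposurePanel,
        yields: pd.DataFrame,
        spec: RegressionSpec | None = None,
        centroids: pd.DataFrame | None = None,
    ):
        self.spec = spec or RegressionSpec()
        self.exposures = exposures
        self.centroids = centroids
        self.design = build_design(exposures, yields, self.spec)
        self._validate_rank()

    @classmethod
    def from_region_map(cls, exposures, yields, regions, spec=None):
        return cls(exposures, yields, spec=spec, centroids=regions.centroids())

    # -- internals ---------------------------------------------------------
    def _within(self):
        d = self.design
        counties, codes = np.unique(d.county, return_inverse=True)
        Xd = _demean_by(d.X.to_numpy(), codes, len(counties))
        yd = _demean_by(d.y.to_numpy(), codes, len(counties))
        return counties, codes, Xd, yd

    def _validate_rank(self) -> None:
        _, _, Xd, _ = self._within()
        norms = np.linalg.norm(Xd, axis=0)
        scale = max(norms.max(), 1.0)
        dead = [c for c, nv in zip(self.design.X.columns, norms) if nv <= 1e-10 * scale]
        if dead:
            raise ValueError(
                f"collinear (constant within county) columns after demeaning: {dead}"
            )
        # pivoted QR exposes any remaining linear dependence and names it
        from scipy.linalg import qr

        _, R, piv = qr(Xd, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Xd.shape) * np.finfo(float).eps * 100
        bad = list(piv[: len(diag)][diag < tol]) + list(piv[len(diag):])
        if len(bad):
            names = [self.design.X.columns[j] for j in sorted(bad)]
            raise ValueError(f"design is rank deficient; offending columns: {names}")

    # -- estimation --------------------------------------------------------
    def fit(self, cov_type: str = "conley", cutoff: float | None = None) -> "BinnedYieldResults":
        """Estimate by within-transformation least squares.

        cov_type: ``conley`` (default; needs centroids), ``hc0`` or ``iid``.
        cutoff: override of the spec's spatial cutoff (degrees).
        """
        d = self.design
        counties, codes, Xd, yd = self._within()
        beta, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
        resid = yd - Xd @ beta

        # county effects from group means of the untransformed data
        n_g = len(counties)
        counts = np.bincount(codes, minlength=n_g).astype(float)
        ybar = np.bincount(codes, weights=d.y.to_numpy(), minlength=n_g) / counts
        xbar = np.stack(
            [np.bincount(codes, weights=col, minlength=n_g) / counts for col in d.X.to_numpy().T],
            axis=1,
        )
        a = ybar - xbar @ beta
        alpha0 = float(a.mean())
        county_effects = pd.Series(a - alpha0, index=pd.Index(counties, name="county_id"))

        k = Xd.shape[1]
        if cov_type == "conley":
            if self.centroids is None:
                raise ValueError("Conley covariance needs county centroids")
            cut = self.spec.spatial_cutoff if cutoff is None else cutoff
            V = conley_vcov(
                Xd,
                resid,
                d.county,
                d.year,
                self.centroids,
                cut,
                metric=self.spec.distance_metric,
                kernel=self.spec.spatial_kernel,
            )
        elif cov_type == "hc0":
            bread = np.linalg.inv(Xd.T @ Xd)
            meat = (Xd * resid[:, None] ** 2).T @ Xd
            V = bread @ meat @ bread
        elif cov_type == "iid":
            dof = d.nobs - k - n_g
            sigma2 = resid @ resid / dof
            V = sigma2 * np.linalg.inv(Xd.T @ Xd)
        else:
            raise ValueError(f"unknown cov_type {cov_type!r}")
        V = (V + V.T) / 2.0

        params = pd.Series(beta, index=d.X.columns, name="estimate")
        vcov = pd.DataFrame(V, index=d.X.columns, columns=d.X.columns)
        return BinnedYieldResults(
            model=self,
            params=params,
            vcov=vcov,
            alpha0=alpha0,
            county_effects=county_effects,
            resid=pd.Series(resid, name="resid"),
            cov_type=cov_type,
        )


class BinnedYieldResults:
    """Estimates, spatial-HAC uncertainties and diagnostics of a fitted panel."""

    def __init__(self, model, params, vcov, alpha0, county_effects, resid, cov_type):
        self.model = model
        self.spec = model.spec
        self.params = params
        self.vcov = vcov
        self.alpha0 = alpha0
        self.county_effects = county_effects
        self.resid = resid
        self.cov_type = cov_type
        self.nobs = model.design.nobs
        self.n_counties = len(county_effects)
        # slope columns + common intercept (county effects reported separately)
        self.n_params = len(params) + 1

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.params.index, name="se")

    def conf_int(self, level: float | None = None) -> pd.DataFrame:
        level = self.spec.ci_level if level is None else level
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = self.bse
        return pd.DataFrame(
            {"lower": self.params - z * se, "upper": self.params + z * se}
        )

    @property
    def temp_cols(self) -> list[str]:
        return self.model.design.temp_cols

    @property
    def gamma(self) -> pd.DataFrame:
        """Per-bin temperature coefficients with SE and CI bounds."""
        ci = self.conf_int()
        out = pd.DataFrame(
            {
                "estimate": self.params[self.temp_cols],
                "se": self.bse[self.temp_cols],
                "lower": ci.loc[self.temp_cols, "lower"],
                "upper": ci.loc[self.temp_cols, "upper"],
            }
        )
        out.index.name = "bin"
        return out

    @property
    def delta(self) -> pd.Series:
        cols = [c for c in ("precip", "precip_sq") if c in self.params.index]
        return self.params[cols]

    @property
    def trend_params(self) -> pd.Series:
        return self.params[[c for c in self.params.index if c.startswith("trend")]]

    def resid_frame(self) -> pd.DataFrame:
        d = self.model.design
        return pd.DataFrame(
            {"county_id": d.county, "year": d.year, "resid": self.resid.to_numpy()}
        )

    def summary(self) -> str:
        d = self.model.design
        lines = [
            "Binned temperature-exposure yield panel (county fixed effects)",
            "=" * 66,
            f"Observations: {self.nobs:>8}    Counties: {self.n_counties}",
            f"Slope params: {len(self.params):>8}    Cov type: {self.cov_type}"
            + (
                f" (cutoff {self.spec.spatial_cutoff} deg)"
                if self.cov_type == "conley"
                else ""
            ),
            f"Response form: {self.spec.response_form}    CI level: {self.spec.ci_level:.0%}",
            "-" * 66,
            f"{'coef':<16}{'estimate':>12}{'se':>10}{'lower':>12}{'upper':>12}",
        ]
        ci = self.conf_int()
        show = self.temp_cols + [c for c in ("precip", "precip_sq") if c in self.params.index]
        for c in show:
            lines.append(
                f"{c:<16}{self.params[c]:>12.5f}{self.bse[c]:>10.5f}"
                f"{ci.loc[c, 'lower']:>12.5f}{ci.loc[c, 'upper']:>12.5f}"
            )
        n_tr = len(self.trend_params)
        lines.append("-" * 66)
        lines.append(
            f"(+ {n_tr} state trend terms, common intercept {self.alpha0:.4f}, "
            f"{self.n_counties} county effects absorbed)"
        )
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def to_csv(self, path) -> None:
        ci = self.conf_int()
        rows = pd.DataFrame(
            {
                "name": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "lower": ci["lower"].to_numpy(),
                "upper": ci["upper"].to_numpy(),
            }
        )
        rows.to_csv(path, index=False)


def _distances(coords: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        diff = coords[:, None, :] - coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))
    if metric == "greatcircle":
        lat = np.radians(coords[:, 0])
        lon = np.radians(coords[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    raise ValueError(f"unknown distance metric {metric!r}")


def conley_vcov(
    X,
    resid,
    county,
    year,
    centroids: pd.DataFrame,
    cutoff: float,
    metric: str = "euclidean",
    kernel: str = "uniform",
) -> np.ndarray:
    """Spatial-HAC sandwich covariance with a distance cutoff.

    ``(X'X)^-1 Omega (X'X)^-1`` where Omega sums ``x_i e_i e_j x_j'`` over
    pairs of observations in the same year whose county centroids lie within
    ``cutoff`` of each other (uniform kernel; optionally Bartlett-tapered).
    With a cutoff below the minimum inter-county distance only self-pairs
    survive and the estimator equals HC0.  No serial (across-year) term.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    X = np.asarray(X, dtype=float)
    resid = np.asarray(resid, dtype=float)
    county = np.asarray(county)
    year = np.asarray(year)
    missing = set(np.unique(county)) - set(centroids.index)
    if missing:
        raise ValueError(f"counties without centroid: {sorted(missing)[:10]}")
    k = X.shape[1]
    omega = np.zeros((k, k))
    for yr in np.unique(year):
        m = year == yr
        Xy = X[m]
        ey = resid[m]
        coords = centroids.loc[county[m], ["lat", "lon"]].to_numpy(float)
        D = _distances(coords, metric)
        if kernel == "uniform":
            W = (D <= cutoff).astype(float)
        elif kernel == "bartlett":
            W = np.clip(1.0 - D / cutoff, 0.0, None) if cutoff > 0 else np.eye(len(ey))
            np.fill_diagonal(W, 1.0)
        else:
            raise ValueError(f"unknown spatial kernel {kernel!r}")
        omega += Xy.T @ (W * np.outer(ey, ey)) @ Xy
    bread = np.linalg.inv(X.T @ X)
    V = bread @ omega @ bread
    return (V + V.T) / 2.0


def ci_overlap_divergence(
    fit_a: BinnedYieldResults, fit_b: BinnedYieldResults, level: float | None = None
) -> tuple[pd.Series, int]:
    """Per-bin significant-divergence flags by the CI-overlap rule.

    Two coefficients diverge significantly iff their confidence intervals
    (closed) are disjoint; a shared endpoint counts as overlapping.
    Returns (flags indexed by bin, total count).  Symmetric in its arguments.
    """
    if fit_a.temp_cols != fit_b.temp_cols:
        raise ValueError("fits use different temperature bins")
    ca = fit_a.conf_int(level).loc[fit_a.temp_cols]
    cb = fit_b.conf_int(level).loc[fit_b.temp_cols]
    flags = (ca["upper"] < cb["lower"]) | (cb["upper"] < ca["lower"])
    flags.name = "divergent"
    flags.index.name = "bin"
    return flags, int(flags.sum())


def ensemble_median(panels: list[pd.DataFrame], label: str = "ensemble-median") -> pd.DataFrame:
    """Per county-year median yield across panel sources.

    Sources missing a county-year are ignored for that entry; an even count
    takes the mean of the two middle values (numpy median convention).
    """
    if not panels:
        raise ValueError("no panels given")
    allp = pd.concat(panels, ignore_index=True)
    keys = ["county_id", "state_id", "year"]
    extra = [c for c in ("scenario", "co2", "regime") if c in allp.columns]
    med = allp.groupby(keys + extra, as_index=False, dropna=False)["yield"].median()
    med["source"] = label
    return med
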