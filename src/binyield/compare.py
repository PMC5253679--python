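"""Observed-vs-simulated response-curve comparison.

Fits the panel model to an observed yield panel, to each simulated panel,
and to their ensemble median, all on the identical county-year subset
(inner join), so that differences between confidence intervals reflect the
yield responses and not the samples.  Significant divergence between two
curves at a bin uses the CI-overlap rule (disjoint intervals).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exposure import ExposurePanel
from .panel import (
    BinnedYieldModel,
    BinnedYieldResults,
    RegressionSpec,
    ci_overlap_divergence,
    ensemble_median,
)

__all__ = ["ComparisonResult", "run_comparison", "exposure_histogram", "curve_frame"]


@dataclass
class ComparisonResult:
    """Fitted response curves and divergence summaries."""

    fits: dict[str, BinnedYieldResults]          # by source label
    curves: pd.DataFrame                         # tidy: source, bin, estimate, lower, upper
    divergence: dict[str, int]                   # pair label -> count of divergent bins
    divergence_flags: dict[str, pd.Series]
    histogram: pd.Series                         # days per bin over the common subset
    n_obs: int


def curve_frame(fits: dict[str, BinnedYieldResults]) -> pd.DataFrame:
    frames = []
    for label, res in fits.items():
        g = res.gamma.reset_index()
        g.insert(0, "source", label)
        frames.append(g[["source", "bin", "estimate", "lower", "upper"]])
    return pd.concat(frames, ignore_index=True)


def exposure_histogram(exposures: ExposurePanel, subset: pd.DataFrame | None = None) -> pd.Series:
    """Total days per pooled bin summed over the county-years of ``subset``.

    ``subset`` is a frame with ``county_id``/``year`` columns (e.g. a yield
    panel); ``None`` uses every exposure record.  An empty subset gives an
    all-zero histogram, so historical and future histograms are always
    comparable on identical bins.
    """
    frame = exposures.frame
    if subset is not None:
        keys = subset[["county_id", "year"]].drop_duplicates()
        frame = frame.merge(keys, on=["county_id", "year"], how="inner")
    hist = frame[list(exposures.bin_labels)].sum()
    hist.name = "days"
    hist.index.name = "bin"
    return hist.reindex(exposures.bin_labels, fill_value=0.0)


def _common_subset(panels: list[pd.DataFrame]) -> pd.DataFrame:
    keys = panels[0][["county_id", "year"]].drop_duplicates()
    for p in panels[1:]:
        keys = keys.merge(p[["county_id", "year"]].drop_duplicates(), on=["county_id", "year"])
    if keys.empty:
        raise ValueError("panels share no county-year observations")
    return keys


def run_comparison(
    observed: pd.DataFrame,
    simulated: list[pd.DataFrame],
    exposures: ExposurePanel,
    spec: RegressionSpec | None = None,
    centroids: pd.DataFrame | None = None,
    sim_labels: list[str] | None = None,
    cov_type: str = "conley",
) -> ComparisonResult:
    """Fit observed, per-model and ensemble-median panels and compare curves.

    All fits run on the inner-join county-year subset of all panels.  The
    divergence summary counts bins whose confidence intervals are disjoint
    for the pair ``observed|ensemble-median`` and, when labels expose a
    rainfed/irrigated pair of simulations, for that pair too.
    """
    if not simulated:
        raise ValueError("need at least one simulated panel")
    if sim_labels is None:
        sim_labels = []
        for i, p in enumerate(simulated):
            src = p["source"].iloc[0] if "source" in p.columns else f"model_{i}"
            sim_labels.append(str(src))
    keys = _common_subset([observed] + list(simulated))
    fits: dict[str, BinnedYieldResults] = {}

    def _fit(panel: pd.DataFrame) -> BinnedYieldResults:
        sub = panel.merge(keys, on=["county_id", "year"])
        model = BinnedYieldModel(exposures, sub, spec=spec, centroids=centroids)
        return model.fit(cov_type=cov_type)

    fits["observed"] = _fit(observed)
    for label, p in zip(sim_labels, simulated):
        fits[label] = _fit(p)
    med = ensemble_median(
        [p.merge(keys, on=["county_id", "year"]) for p in simulated]
    )
    fits["ensemble-median"] = _fit(med)

    n_obs = {label: f.nobs for label, f in fits.items()}
    if len(set(n_obs.values())) != 1:
        raise AssertionError(f"compared fits use different samples: {n_obs}")

    divergence: dict[str, int] = {}
    divergence_flags: dict[str, pd.Series] = {}
    flags, count = ci_overlap_divergence(fits["observed"], fits["ensemble-median"])
    divergence["observed|ensemble-median"] = count
    divergence_flags["observed|ensemble-median"] = flags
    regimes = {}
    for label, p in zip(sim_labels, simulated):
        if "regime" in p.columns:
            regimes.setdefault(p["regime"].iloc[0], label)
    if {"rainfed", "irrigated"} <= set(regimes):
        pair = f"{regimes['rainfed']}|{regimes['irrigated']}"
        flags, count = ci_overlap_divergence(fits[regimes["rainfed"]], fits[regimes["irrigated"]])
        divergence[pair] = count
        divergence_flags[pair] = flags

    return ComparisonResult(
        fits=fits,
        curves=curve_frame(fits),
        divergence=divergence,
        divergence_flags=divergence_flags,
        histogram=exposure_histogram(exposures, keys),
        n_obs=next(iter(n_obs.values())),
    )
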