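"""Temperature-range yield change factors and the future-loss decomposition.

A fitted bin coefficient gamma_h is a log-yield change per day of exposure;
combining it with the mean per-season exposure E_h gives a multiplicative
change factor exp(sum_h gamma_h * E_h) for any temperature range whose
boundaries fall on bin edges.  The canonical split is <30 degC (no stress),
30-36 degC (medium high temperature) and >36 degC (extreme high
temperature).  The future yield loss attributable to exposure shifts below
36 degC is one minus the ratio of the future to the historical product of
the <30 and 30-36 factors; the >36 factors never enter it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bins import BinScheme

__all__ = [
    "ChangeFactors",
    "per_day_effect",
    "change_factor",
    "change_factors",
    "future_loss_below36",
    "factors_table",
]

RANGES = {"below30": (0.0, 30.0), "r30_36": (30.0, 36.0), "above36": (36.0, 42.0)}


@dataclass(frozen=True)
class ChangeFactors:
    """Multiplicative yield factors per temperature range, for one crop/period."""

    crop: str
    period: str  # "historical" | "future"
    factor_below30: float
    factor_30_36: float
    factor_above36: float

    def __post_init__(self) -> None:
        for f in (self.factor_below30, self.factor_30_36, self.factor_above36):
            if not f > 0:
                raise ValueError("change factors must be positive")

    @property
    def total(self) -> float:
        """Product of all temperature-range factors (exposure >0 degC)."""
        return self.factor_below30 * self.factor_30_36 * self.factor_above36


def per_day_effect(gamma_h: float) -> float:
    """Fractional yield change from one extra day in a bin (positive = loss).

    ``1 - exp(gamma_h)``: e.g. gamma = -0.04 means one additional day at
    those temperatures reduces yield by about 4%.
    """
    return 1.0 - float(np.exp(gamma_h))


def _range_mask(scheme: BinScheme, lo: float, hi: float) -> list[str]:
    edges = scheme.pooled_edges
    top = scheme.pool_top_at
    for bound in (lo, min(hi, top + scheme.pooled_width)):
        onto = np.concatenate([edges, [top + scheme.pooled_width]])
        if not np.any(np.isclose(onto, bound)):
            raise ValueError(f"range boundary {bound} does not fall on a pooled bin edge")
    labels = []
    lows = np.append(edges[:-1], top)
    for low, lab in zip(lows, scheme.pooled_labels):
        if lo <= low < hi:
            labels.append(lab)
    return labels


def change_factor(
    gamma: pd.Series, mean_exposure: pd.Series, temp_range: tuple[float, float],
    scheme: BinScheme | None = None,
) -> float:
    """Multiplicative yield factor for one temperature range.

    ``exp(sum_h gamma_h * E_h)`` over pooled bins h inside ``temp_range``
    (boundaries must fall on pooled bin edges, e.g. 30 and 36), where ``E_h``
    is the mean per-season exposure in days.
    """
    scheme = scheme or BinScheme()
    labels = _range_mask(scheme, *temp_range)
    missing = [b for b in labels if b not in gamma.index or b not in mean_exposure.index]
    if missing:
        raise ValueError(f"bins missing from gamma/exposure: {missing}")
    expo = sum(float(gamma[b]) * float(mean_exposure[b]) for b in labels)
    return float(np.exp(expo))


def change_factors(
    gamma: pd.Series,
    mean_exposure: pd.Series,
    crop: str,
    period: str,
    scheme: BinScheme | None = None,
) -> ChangeFactors:
    """All three canonical range factors from fitted coefficients and exposures.

    ``mean_exposure`` is the mean over county-years of the panel (counties
    weighted equally) of the days per pooled bin per season.
    """
    scheme = scheme or BinScheme()
    return ChangeFactors(
        crop=crop,
        period=period,
        factor_below30=change_factor(gamma, mean_exposure, RANGES["below30"], scheme),
        factor_30_36=change_factor(gamma, mean_exposure, RANGES["r30_36"], scheme),
        factor_above36=change_factor(gamma, mean_exposure, RANGES["above36"], scheme),
    )


def future_loss_below36(hist: ChangeFactors, fut: ChangeFactors, as_percent: bool = True) -> float:
    """Yield loss from exposure shifts within 0-36 degC, historical -> future.

    ``1 - (fut.below30 * fut.30_36) / (hist.below30 * hist.30_36)``; the
    >36 degC factors do not enter by construction.  Returned as percent by
    default (full precision; round for tabulation).
    """
    if hist.crop != fut.crop:
        raise ValueError(f"crop mismatch: {hist.crop!r} vs {fut.crop!r}")
    num = fut.factor_below30 * fut.factor_30_36
    den = hist.factor_below30 * hist.factor_30_36
    if not (num > 0 and den > 0):
        raise ValueError("change factors must be positive")
    loss = 1.0 - num / den
    return 100.0 * loss if as_percent else loss


def factors_table(pairs: list[tuple[ChangeFactors, ChangeFactors]]) -> pd.DataFrame:
    """Report table: one (historical, future) row pair per crop plus the loss.

    Factors and totals are rounded to two decimals and the loss to the
    nearest integer percent for report parity; compute from the unrounded
    objects if full precision is needed.
    """
    rows = []
    for hist, fut in pairs:
        loss = round(future_loss_below36(hist, fut))
        for cf in (hist, fut):
            rows.append(
                {
                    "crop": cf.crop,
                    "period": cf.period,
                    "below30": round(cf.factor_below30, 2),
                    "f30_36": round(cf.factor_30_36, 2),
                    "above36": round(cf.factor_above36, 2),
                    "total": round(cf.total, 2),
                    "future_loss_below36_pct": loss if cf.period == "historical" else "",
                }
            )
    return pd.DataFrame(rows)
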