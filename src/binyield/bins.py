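"""Within-day temperature-bin exposure from daily Tmin/Tmax.

The diurnal temperature course on each calendar day is modelled as a
sinusoid between that day's minimum and maximum,

    T(t) = M + A * sin(2*pi*t),   M = (tmax + tmin) / 2,  A = (tmax - tmin) / 2,

which yields a closed form for the fraction of the day spent above any
threshold, and hence (by differencing) the time spent inside each
temperature bin.  Fine 1 degC bins are pooled to 3 K bins for the
regression; everything above ``pool_top_at`` is subsumed into a single
top bin and time below the lower limit (0 degC) is excluded from the
covariates (its effect is absorbed by the regression intercept).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinScheme",
    "fraction_above",
    "time_in_bins",
    "pool_fine_to_scheme",
]


@dataclass(frozen=True)
class BinScheme:
    """Fine and pooled temperature bins used for exposure covariates.

    Pooled bins are half-open ``[low, high)`` intervals of width
    ``pooled_width`` from ``lower_limit`` up to ``pool_top_at``; all time at
    temperatures >= ``pool_top_at`` falls into one open-ended top bin
    (labelled as ``pool_top_at``..``pool_top_at + pooled_width``, e.g.
    ``bin_39_42``).  Time below ``lower_limit`` is tracked separately and is
    never a covariate.
    """

    fine_width: float = 1.0
    pooled_width: float = 3.0
    lower_limit: float = 0.0
    pool_top_at: float = 39.0
    top_bin_mean: float = 40.0  # mean temperature of pooled >top time, for degree-day midpoints

    def __post_init__(self) -> None:
        if self.fine_width <= 0 or self.pooled_width <= 0:
            raise ValueError("bin widths must be positive")
        span = self.pool_top_at - self.lower_limit
        if span <= 0:
            raise ValueError("pool_top_at must exceed lower_limit")
        if abs(span / self.pooled_width - round(span / self.pooled_width)) > 1e-9:
            raise ValueError("pooled_width must evenly divide the bin span")
        if abs(span / self.fine_width - round(span / self.fine_width)) > 1e-9:
            raise ValueError("fine_width must evenly divide the bin span")

    @property
    def fine_edges(self) -> np.ndarray:
        """Interior fine-bin edges from lower_limit to pool_top_at inclusive."""
        n = int(round((self.pool_top_at - self.lower_limit) / self.fine_width))
        return self.lower_limit + self.fine_width * np.arange(n + 1)

    @property
    def pooled_edges(self) -> np.ndarray:
        n = int(round((self.pool_top_at - self.lower_limit) / self.pooled_width))
        return self.lower_limit + self.pooled_width * np.arange(n + 1)

    @property
    def pooled_labels(self) -> list[str]:
        """Column labels, e.g. ``bin_0_3`` ... ``bin_36_39``, ``bin_39_42``."""
        edges = self.pooled_edges
        labels = [
            f"bin_{_fmt(lo)}_{_fmt(hi)}" for lo, hi in zip(edges[:-1], edges[1:])
        ]
        labels.append(f"bin_{_fmt(self.pool_top_at)}_{_fmt(self.pool_top_at + self.pooled_width)}")
        return labels

    @property
    def n_pooled(self) -> int:
        return len(self.pooled_labels)

    @property
    def fine_midpoints(self) -> np.ndarray:
        """Midpoints of the fine bins plus the top-bin mean, for degree-day sums."""
        edges = self.fine_edges
        mids = (edges[:-1] + edges[1:]) / 2.0
        return np.append(mids, self.top_bin_mean)

    def pooled_label_for(self, temperature: float) -> str:
        """Label of the pooled bin containing ``temperature`` (>= lower_limit)."""
        if temperature < self.lower_limit:
            raise ValueError(f"temperature {temperature} below the lower limit")
        idx = int((min(temperature, self.pool_top_at) - self.lower_limit) // self.pooled_width)
        return self.pooled_labels[min(idx, self.n_pooled - 1)]


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x).replace(".", "p")


def fraction_above(tmin, tmax, threshold):
    """Fraction of one day the diurnal sinusoid spends above ``threshold``.

    With M = (tmax+tmin)/2 and A = (tmax-tmin)/2 the sinusoid
    M + A*sin(2*pi*t) exceeds the threshold for a fraction

        1/2 - arcsin((threshold - M) / A) / pi

    of the day when tmin < threshold < tmax; the fraction saturates at 1
    (threshold <= tmin) and 0 (threshold >= tmax).  A degenerate flat day
    (tmax == tmin) contributes the indicator of tmin > threshold.

    All arguments broadcast as numpy arrays; scalars in give a scalar out.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    threshold = np.asarray(threshold, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin encountered")
    mid = (tmax + tmin) / 2.0
    amp = (tmax - tmin) / 2.0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = np.clip(np.where(amp > 0, (threshold - mid) / np.where(amp > 0, amp, 1.0), 0.0), -1.0, 1.0)
        interior = 0.5 - np.arcsin(z) / np.pi
    frac = np.where(
        threshold <= tmin,
        1.0,
        np.where(threshold >= tmax, 0.0, interior),
    )
    # flat day: all-or-nothing
    frac = np.where((amp == 0), (tmin > threshold).astype(float), frac)
    if frac.ndim == 0:
        return float(frac)
    return frac


def time_in_bins(tmin, tmax, scheme: BinScheme | None = None):
    """Days spent per fine bin for one (vector of) day(s).

    Returns ``(below, fine, top)`` where ``fine`` has one entry per fine bin
    between ``lower_limit`` and ``pool_top_at``, ``below`` is the time below
    the lower limit and ``top`` the time at or above ``pool_top_at``.  The
    three parts always sum to exactly one day per input day (telescoping sum
    of the fraction-above CDF).

    ``tmin``/``tmax`` may be scalars or 1-d arrays of equal length; with
    array input each of the three returns gains a leading day axis.
    """
    scheme = scheme or BinScheme()
    tmin = np.atleast_1d(np.asarray(tmin, dtype=float))
    tmax = np.atleast_1d(np.asarray(tmax, dtype=float))
    edges = scheme.fine_edges
    # fraction above each edge: shape (n_days, n_edges)
    fa = fraction_above(tmin[:, None], tmax[:, None], edges[None, :])
    fa = np.atleast_2d(fa)
    below = 1.0 - fa[:, 0]
    top = fa[:, -1]
    fine = fa[:, :-1] - fa[:, 1:]
    return below, fine, top


def pool_fine_to_scheme(below, fine, top, scheme: BinScheme) -> np.ndarray:
    """Pool fine-bin times to the 3 K covariate bins (top bin appended).

    ``fine`` is (n_days, n_fine) or (n_fine,); the result sums over days,
    giving one value per pooled label.  Below-limit time is not pooled (it is
    excluded from the covariates) but is accepted for signature symmetry.
    """
    fine = np.atleast_2d(fine)
    per_pool = int(round(scheme.pooled_width / scheme.fine_width))
    n_pool = scheme.n_pooled - 1
    pooled = fine.sum(axis=0).reshape(n_pool, per_pool).sum(axis=1)
    return np.append(pooled, np.atleast_1d(top).sum())
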