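"""Coefficient-curve and exposure-histogram figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_response_curves"]

_COLORS = {"observed": "black", "ensemble-median": "tab:green"}


def plot_response_curves(curves: pd.DataFrame, histogram: pd.Series | None = None, title: str = ""):
    """Per-bin coefficient curves with CI bands, plus an exposure histogram.

    ``curves`` is the tidy frame from the comparison (source, bin, estimate,
    lower, upper); returns the matplotlib Figure (save with ``fig.savefig``,
    e.g. to PDF/SVG for vector output).
    """
    nrows = 2 if histogram is not None else 1
    fig, axes = plt.subplots(
        nrows, 1, figsize=(7, 3.2 * nrows), sharex=True,
        gridspec_kw={"height_ratios": [3, 1]} if nrows == 2 else None,
    )
    ax = axes[0] if nrows == 2 else axes
    bins = curves["bin"].drop_duplicates().tolist()
    x = np.arange(len(bins))
    for i, (source, grp) in enumerate(curves.groupby("source", sort=False)):
        grp = grp.set_index("bin").reindex(bins)
        color = _COLORS.get(source, f"C{i}")
        ax.plot(x, grp["estimate"], marker="o", ms=3, label=source, color=color)
        ax.fill_between(x, grp["lower"], grp["upper"], alpha=0.15, color=color)
    ax.axhline(0.0, lw=0.6, color="grey")
    ax.set_ylabel("log-yield change per day")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    if histogram is not None:
        axh = axes[1]
        axh.bar(x, histogram.reindex(bins).to_numpy(), color="tab:grey")
        axh.set_ylabel("days")
    (axes[-1] if nrows == 2 else ax).set_xticks(x)
    (axes[-1] if nrows == 2 else ax).set_xticklabels(
        [b.removeprefix("bin_").replace("_", "-") for b in bins], rotation=60, fontsize=7
    )
    fig.tight_layout()
    return fig
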