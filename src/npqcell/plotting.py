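"""Matplotlib figures for scores, distances and grid-trace maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .heterogeneity import GridTraceMap, RepeatDistanceResult, TrendResult
from .npqspace import AXES, ScoreSet

POP_COLORS = {"Pop0": "tab:blue", "PopQE": "tab:orange",
              "PopQT": "tab:green", "PopQI": "tab:purple",
              "WT": "tab:gray"}


def plot_score_scatter(scores: ScoreSet, axes: tuple[str, str] = ("qT", "qE"),
                       trend: TrendResult | None = None, ax=None):
    """2D projection of the NPQ score cloud, colored by population."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x, y = scores.axis(axes[0]), scores.axis(axes[1])
    labs = np.asarray(scores.labels)
    for pop in dict.fromkeys(scores.labels):
        sel = labs == pop
        ax.scatter(x[sel], y[sel], s=8, alpha=0.6,
                   color=POP_COLORS.get(pop, None), label=pop)
    if trend is not None:
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, trend.slope * xs + trend.intercept, "k-", lw=1,
                label=f"fit (r={trend.r:.2f})")
    ax.set_xlabel(f"q̃{axes[0][1:]}" if axes[0].startswith("q") else axes[0])
    ax.set_ylabel(f"q̃{axes[1][1:]}" if axes[1].startswith("q") else axes[1])
    ax.legend(fontsize=7)
    return ax


def plot_distance_histograms(result: RepeatDistanceResult, ax=None):
    """D_ii vs D_ij histograms from a repeat-pair analysis."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    bins = np.linspace(0, max(result.D_ij.max(), 1e-12), 40)
    ax.hist(result.D_ij, bins=bins, density=True, alpha=0.5, color="k",
            label=f"D_ij (sd={result.sd_ij:.2g})")
    ax.hist(result.D_ii, bins=bins, density=True, alpha=0.6, color="tab:blue",
            label=f"D_ii (sd={result.sd_ii:.2g})")
    ax.set_xlabel("distance in NPQ space")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    return ax


def plot_grid_traces(gmap: GridTraceMap, fig=None):
    """Panel of average display-normalized traces per occupied grid box."""
    if fig is None:
        fig = plt.figure(figsize=(8, 8))
    n = gmap.grid_n
    for (gx, gy), trace in gmap.mean_traces.items():
        # row 0 at the top = largest y bin
        ax = fig.add_subplot(n, n, (n - 1 - gy) * n + gx + 1)
        ax.plot(trace, lw=0.8)
        ax.set_xticks([])
        ax.set_yticks([])
    return fig
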