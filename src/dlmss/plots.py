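"""Scatter and density visualizations of tracklets in S_MSS–D space."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.gridspec import GridSpec

from .mobility import MobilitySummary, kde_map
from .tracklets import TrackletRecord

__all__ = ["plot_scatter", "plot_kde"]

_CLASS_COLORS = {0: "tab:red", 1: "tab:blue", 2: "0.5"}
_CLASS_NAMES = {0: "fast", 1: "slow", 2: "immobile"}


def _points(tracklets: list[TrackletRecord]):
    pts = [
        (t.S_mss, t.D, t.label)
        for t in tracklets
        if t.included_in_clustering and t.S_mss is not None and t.D is not None and t.D > 0
    ]
    if not pts:
        raise ValueError("no clustering-eligible tracklets to plot")
    arr = np.array([(s, d) for s, d, _ in pts])
    labs = np.array([l for _, _, l in pts])
    return arr, labs


def plot_scatter(
    tracklets: list[TrackletRecord],
    summary: MobilitySummary | None = None,
    path: str | None = None,
    bins: int = 30,
):
    """Scatterplot of tracklets in S_MSS–D space, colored by class, with
    side histograms and '+' marks at the cluster means."""
    arr, labs = _points(tracklets)
    logd = np.log10(arr[:, 1])
    fig = plt.figure(figsize=(6.5, 6))
    gs = GridSpec(2, 2, width_ratios=[4, 1], height_ratios=[1, 4], hspace=0.05, wspace=0.05)
    ax = fig.add_subplot(gs[1, 0])
    ax_top = fig.add_subplot(gs[0, 0], sharex=ax)
    ax_right = fig.add_subplot(gs[1, 1], sharey=ax)
    sbins = np.linspace(arr[:, 0].min(), arr[:, 0].max(), bins + 1)
    dbins = np.linspace(logd.min(), logd.max(), bins + 1)
    for lab in sorted(set(labs)):
        sel = labs == lab
        color = _CLASS_COLORS.get(lab, None)
        name = _CLASS_NAMES.get(lab, str(lab))
        ax.scatter(arr[sel, 0], logd[sel], s=6, alpha=0.5, color=color, label=name)
        ax_top.hist(arr[sel, 0], bins=sbins, histtype="step", color=color)
        ax_right.hist(logd[sel], bins=dbins, histtype="step", color=color,
                      orientation="horizontal")
    if summary is not None:
        for lab, cs in summary.per_class.items():
            if cs.mean_S_mss is not None and cs.mean_D is not None and cs.mean_D > 0:
                ax.plot(cs.mean_S_mss, np.log10(cs.mean_D), "+", color="k", ms=14, mew=2)
    ax.set_xlabel(r"$S_{MSS}$")
    ax.set_ylabel(r"$\log_{10} D$ ($\mu m^2/s$)")
    ax.legend(loc="best", fontsize=8)
    plt.setp(ax_top.get_xticklabels(), visible=False)
    plt.setp(ax_right.get_yticklabels(), visible=False)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_kde(tracklets: list[TrackletRecord], path: str | None = None, grid_size: int = 128):
    """Joint kernel-density map over all clustering-eligible tracklets."""
    arr, _ = _points(tracklets)
    km = kde_map(arr, grid_size=grid_size, log_d=True)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.pcolormesh(km.s_grid, km.d_grid, km.density.T, cmap="viridis", shading="auto")
    fig.colorbar(im, ax=ax, label="density")
    ax.set_xlabel(r"$S_{MSS}$")
    ax.set_ylabel(r"$\log_{10} D$ ($\mu m^2/s$)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
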