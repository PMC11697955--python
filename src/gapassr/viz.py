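"""Figure helpers: time-frequency heatmaps and ITPC summaries.

Figures are secondary outputs (the CSV tables are the canonical surface);
styling follows the conventions of the source experiments — warm colors
for high power/ITPC, significant-cluster contours on difference maps,
standard-deviation error bars on group summaries.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_map", "plot_difference_map", "plot_itpc_by_width"]


def _extent(freqs, times):
    return [times[0], times[-1], freqs[0], freqs[-1]]


def plot_map(values, freqs, times, title="", cbar_label="", ax=None):
    """Heatmap of a time x frequency map (warm = high)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    im = ax.imshow(
        values, aspect="auto", origin="lower", extent=_extent(freqs, times),
        cmap="turbo",
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(title)
    plt.colorbar(im, ax=ax, label=cbar_label)
    return ax


def plot_difference_map(result, freqs, times, title="", ax=None):
    """Group difference t-map with contours around significant clusters."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    im = ax.imshow(
        result.t_map, aspect="auto", origin="lower",
        extent=_extent(freqs, times), cmap="RdBu_r",
        vmin=-np.nanmax(np.abs(result.t_map)), vmax=np.nanmax(np.abs(result.t_map)),
    )
    for c in result.significant:
        ax.contour(
            times, freqs, c.mask.astype(float), levels=[0.5],
            colors="k", linewidths=1.2,
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(title)
    plt.colorbar(im, ax=ax, label="t")
    return ax


def plot_itpc_by_width(cohort: pd.DataFrame, region: str, ax=None):
    """Group-mean 40 Hz ITPC vs gap width with SD error bars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    sub = cohort[cohort["region"] == region]
    for (g, t), grp in sub.groupby(["genotype", "treatment"]):
        agg = grp.groupby("gap_width_ms")["value"].agg(["mean", "std"])
        ax.errorbar(
            agg.index, agg["mean"], yerr=agg["std"], marker="o", capsize=2,
            label=f"{g}-{t}",
        )
    ax.set_xlabel("gap width (ms)")
    ax.set_ylabel("mean 40 Hz ITPC")
    ax.set_ylim(0, 1)
    ax.set_title(region)
    ax.legend(fontsize=7)
    return ax
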