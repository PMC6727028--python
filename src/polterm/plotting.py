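"""Plots for metagene curves and shortening statistics (matplotlib, Agg)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .metagene import GroupCurve, N_FLANK_BINS, N_BODY_BINS

_BAND_COLORS = {"red": "#d62728", "orange": "#ff7f0e", "yellow": "#ffd700", "none": "#ffffff"}


def plot_metagene(curve: GroupCurve, path: str, title: str = "") -> None:
    """Control/treated metagene curves with the significance band track."""
    fig, (ax, axb) = plt.subplots(
        2, 1, figsize=(8, 4.5), sharex=True, height_ratios=[10, 1]
    )
    x = np.arange(len(curve.ctrl_mean))
    ax.plot(x, curve.ctrl_mean, color="tab:blue", label="control")
    ax.plot(x, curve.treated_mean, color="tab:red", label="treated")
    for edge in (N_FLANK_BINS, N_FLANK_BINS + N_BODY_BINS):
        ax.axvline(edge, ls=":", color="grey", lw=0.8)
    ax.set_ylabel("mean normalized occupancy")
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    axb.bar(x, np.ones_like(x), width=1.0,
            color=[_BAND_COLORS[b] for b in curve.bands], edgecolor="none")
    axb.set_yticks([])
    axb.set_xlabel("bin (TSS-3kb | scaled body | TTS+3kb)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_shortening_curve(df: pd.DataFrame, path: str) -> None:
    """Per-length-quantile cumulative shortening curves."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for gidx, sub in df.groupby("group"):
        ax.plot(sub["grid"], 100 * sub["fraction"], label=f"quantile {gidx + 1}")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("relative Δ90% distance")
    ax.set_ylabel("% genes with Δ ≥ x")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
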