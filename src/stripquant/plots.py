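"""Matplotlib renderings of the agreement and trend analyses."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .validation_stats import BlandAltmanResult, PairedSeries

__all__ = ["plot_bland_altman", "plot_site_series"]


def plot_bland_altman(
    s: PairedSeries, result: BlandAltmanResult, path: str | Path, title: str = ""
) -> Path:
    """Scatter of per-sample differences against pair means with bias and
    limits-of-agreement lines."""
    import numpy as np

    a, b = np.asarray(s.values_a), np.asarray(s.values_b)
    means, diffs = (a + b) / 2.0, a - b
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=18, alpha=0.8)
    ax.axhline(result.bias, color="tab:blue", label=f"bias = {result.bias:.3g}")
    for loa, name in ((result.loa_low, "LoA low"), (result.loa_high, "LoA high")):
        ax.axhline(loa, color="tab:red", linestyle="--", label=f"{name} = {loa:.3g}")
    ax.set_xlabel(f"mean of {s.label_a} and {s.label_b}")
    ax.set_ylabel(f"{s.label_a} - {s.label_b}")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_site_series(table: pd.DataFrame, path: str | Path, cumulative: bool = False) -> Path:
    """Standardized (or cumulative) concentration profiles along the transect."""
    col = "cumulative" if cumulative and "cumulative" in table.columns else "standardized"
    fig, ax = plt.subplots(figsize=(7, 4))
    for analyte, sub in table.groupby("analyte", sort=False):
        ax.plot(sub["site_order"], sub[col], marker="o", markersize=3, label=analyte)
    ax.set_xlabel("site location along transect")
    ax.set_ylabel("cumulative standardized value" if col == "cumulative" else "standardized value")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
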