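"""Optional figures: scaled box plots and Dunn comparison-interval charts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .features import STAT_FEATURES
from .group_stats import PH_GROUP_ORDER

__all__ = ["boxplots", "comparison_intervals"]


def boxplots(features: pd.DataFrame, path: str | Path) -> None:
    """Per-feature box plots with values scaled to [0, 1] per feature."""
    cols = [c for c in STAT_FEATURES if c in features.columns]
    groups = [g for g in PH_GROUP_ORDER if g in set(features["group"])]
    fig, axes = plt.subplots(2, 5, figsize=(16, 6), sharey=True)
    for ax, col in zip(axes.ravel(), cols):
        v = features[col].astype(float)
        span = v.max() - v.min()
        scaled = (v - v.min()) / span if span > 0 else v * 0 + 0.5
        data = [scaled[features["group"] == g].dropna() for g in groups]
        ax.boxplot(data, tick_labels=groups, showmeans=True)
        ax.set_title(col)
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def comparison_intervals(report: dict, feature: str, path: str | Path) -> None:
    """Mean-rank estimates with simultaneous intervals for one feature.

    Disjoint intervals indicate a significant pairwise difference.
    """
    entry = report["features"][feature]
    groups = entry["groups"]
    pairs = entry.get("pairs", [])
    half = {}
    for p in pairs:
        w = (p["upper"] - p["lower"]) / 2.0
        half[p["i"]] = max(half.get(p["i"], 0.0), w / np.sqrt(2))
        half[p["j"]] = max(half.get(p["j"], 0.0), w / np.sqrt(2))
    fig, ax = plt.subplots(figsize=(6, 3))
    for y, g in enumerate(groups):
        label, mr = g["label"], g["mean_rank"]
        h = half.get(label, 0.0)
        sig = any(p["significant"] and label in (p["i"], p["j"]) for p in pairs)
        color = "tab:red" if sig else "tab:blue"
        ax.plot([mr - h, mr + h], [y, y], color=color, lw=2)
        ax.plot(mr, y, "o", color=color)
    ax.set_yticks(range(len(groups)), [g["label"] for g in groups])
    ax.set_xlabel("mean rank")
    ax.set_title(feature)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
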