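"""Plots for screen results: content/bio-active heatmaps, AI ranking, dual scores."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless batch plotting

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_content_map", "plot_bioactive_map", "plot_ai_ranking",
           "plot_dual_scores"]


def _heatmap(ax, matrix: pd.DataFrame, cmap: str, title: str):
    im = ax.imshow(matrix.values, aspect="auto", cmap=cmap)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    ax.set_xlabel("compound")
    ax.set_ylabel("fraction")
    ax.set_title(title)
    return im


def plot_content_map(normalized: pd.DataFrame, ax=None):
    """Relative-content heatmap: each compound's share per fraction."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    im = _heatmap(ax, normalized, "viridis", "relative content")
    plt.colorbar(im, ax=ax, label="share of compound total")
    return ax


def plot_bioactive_map(bmap: pd.DataFrame, ax=None):
    """Bio-active map: content reweighted by fraction recovery (diverging)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    lim = float(np.abs(bmap.values).max()) or 1.0
    im = ax.imshow(bmap.values, aspect="auto", cmap="RdGy_r", vmin=-lim, vmax=lim)
    ax.set_yticks(range(len(bmap.index)), bmap.index)
    ax.set_xlabel("compound")
    ax.set_ylabel("fraction")
    ax.set_title("bio-active map")
    plt.colorbar(im, ax=ax, label="R_i x content share (%)")
    return ax


def plot_ai_ranking(scores: pd.DataFrame, top: int | None = None, ax=None):
    """Horizontal bar chart of activity indexes, best first."""
    ordered = scores.sort_values("rank")
    if top:
        ordered = ordered.head(top)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.25 * len(ordered) + 1))
    colors = np.where(ordered["AI"] > 0, "#b2182b", "#878787")
    ax.barh(range(len(ordered)), ordered["AI"], color=colors)
    ax.set_yticks(range(len(ordered)), ordered.index)
    ax.invert_yaxis()
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("activity index (%)")
    return ax


def plot_dual_scores(dual: pd.DataFrame, annotate: bool = True, ax=None):
    """Cell-protection AI (x) vs heart-rate AI (y); upper right is best."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(dual["cell_AI"], dual["zebrafish_AI"], s=18, alpha=0.8)
    if annotate:
        best = dual[(dual["cell_AI"] > 0) & (dual["zebrafish_AI"] > 0)]
        for cid, row in best.iterrows():
            ax.annotate(str(cid), (row["cell_AI"], row["zebrafish_AI"]),
                        fontsize=7, xytext=(2, 2), textcoords="offset points")
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("cell-protection AI (%)")
    ax.set_ylabel("heart-rate recovery AI (%)")
    return ax
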