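"""Rendering: barcode heatmaps, dendrogram, metric curves, composition pies."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram as _scipy_dendrogram

from .barcode import BarcodePanel
from .diagnostics import CompositionTable
from .hcluster import Dendrogram

__all__ = ["plot_barcode", "plot_dendrogram", "plot_metrics", "plot_composition_pies"]


def plot_barcode(panel: BarcodePanel, path, title: str | None = None) -> None:
    """Blue-white-red heatmap, variables as category-ordered rows, blanks empty."""
    order = panel.groups.sort_values(kind="stable").index.tolist()
    vals = panel.display_values()[order].T  # variables x clusters
    if panel.kind == "means":
        vmin, vmax, center_lab = 0.0, 1.0, "mean normalized value"
    else:
        lim = max(3.0, float(np.nanmax(np.abs(vals.to_numpy()))) if vals.notna().any().any() else 3.0)
        vmin, vmax, center_lab = -lim, lim, "z (SDs from resampled mean)"
    fig, ax = plt.subplots(figsize=(max(4, 1.2 * vals.shape[1]), max(6, 0.16 * vals.shape[0])))
    masked = np.ma.masked_invalid(vals.to_numpy(dtype=float))
    cmap = plt.get_cmap("bwr").copy()
    cmap.set_bad("white")
    im = ax.imshow(masked, aspect="auto", cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_xticks(range(vals.shape[1]), [str(c) for c in vals.columns])
    ax.set_yticks(range(vals.shape[0]), vals.index, fontsize=4)
    ax.set_xlabel("cluster")
    fig.colorbar(im, ax=ax, label=center_lab)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dendrogram(tree: Dendrogram, path, max_leaves: int = 30) -> None:
    fig, ax = plt.subplots(figsize=(10, 5))
    _scipy_dendrogram(tree.merges, truncate_mode="lastp", p=max_leaves, ax=ax, no_labels=True)
    ax.set_ylabel(f"{tree.method} linkage height")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_metrics(metrics: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    for col in metrics.columns:
        series = metrics[col]
        finite = series.replace([np.inf, -np.inf], np.nan)
        denom = np.nanmax(np.abs(finite.to_numpy())) or 1.0
        ax.plot(metrics.index, finite / denom, marker="o", label=f"{col} (scaled)")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("metric (max-scaled)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_composition_pies(comp: CompositionTable, path, what: str = "diagnosis") -> None:
    frame = comp.diagnosis if what == "diagnosis" else comp.centers
    clusters = sorted(frame["cluster"].unique())
    ncol = min(4, len(clusters))
    nrow = int(np.ceil(len(clusters) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.2 * nrow))
    axes = np.atleast_1d(axes).ravel()
    for ax in axes[len(clusters):]:
        ax.axis("off")
    for ax, c in zip(axes, clusters):
        sub = frame[frame["cluster"] == c]
        if what == "diagnosis":
            slices = sub.groupby("diagnosis")["proportion"].sum()
        else:
            slices = sub.set_index("center")["proportion"]
        ax.pie(slices.to_numpy(), labels=[str(x) for x in slices.index], textprops={"fontsize": 7})
        ax.set_title(f"cluster {c}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
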