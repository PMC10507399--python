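"""Figure exports for a pipeline run.

All plots use a colourblind-accessible palette and are written as PNG next
to the CSVs they visualise: the cluster-count-vs-DBI sweep scatter used for
resolution selection, UMAPs coloured by cluster / split by batch /
per-marker feature intensity, per-cluster dispersion panels, and the
frequency and median-expression heatmaps used for annotation.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_sweep",
    "plot_umap_clusters",
    "plot_umap_by_batch",
    "plot_feature_umaps",
    "plot_cluster_dispersion",
    "plot_heatmap",
]

# Okabe-Ito plus extensions; cycles when clusters exceed the palette.
_PALETTE = [
    "#E69F00", "#56B4E9", "#009E73", "#F0E442", "#0072B2",
    "#D55E00", "#CC79A7", "#999999", "#000000", "#8DD3C7",
    "#BEBADA", "#FB8072", "#80B1D3", "#FDB462", "#B3DE69",
]


def _color(i: int) -> str:
    return _PALETTE[i % len(_PALETTE)]


def plot_sweep(sweep_table: pd.DataFrame, out_path: str | Path) -> Path:
    """Cluster count vs DBI scatter (the grid-selection plot)."""
    ok = sweep_table[~sweep_table["failed"]]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ok["n_clusters_total"], ok["dbi"], "o-", color=_PALETTE[4])
    for _, r in ok.iterrows():
        ax.annotate(
            f"{int(r['xdim'])}x{int(r['ydim'])}",
            (r["n_clusters_total"], r["dbi"]),
            textcoords="offset points", xytext=(4, 4), fontsize=7,
        )
    ax.set_xlabel("cluster count (grid size)")
    ax.set_ylabel("Davies-Bouldin index")
    ax.set_title("Cluster count vs DBI")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def _umap_scatter(ax, coords: np.ndarray, colors, **kw):
    ax.scatter(coords[:, 0], coords[:, 1], s=2, c=colors, linewidths=0, **kw)
    ax.set_xlabel("UMAP1")
    ax.set_ylabel("UMAP2")


def plot_umap_clusters(cell_meta: pd.DataFrame, out_path: str | Path) -> Path:
    coords = cell_meta[["umap1", "umap2"]].to_numpy()
    labels = cell_meta["cluster"].to_numpy()
    fig, ax = plt.subplots(figsize=(6, 5))
    for i, c in enumerate(np.unique(labels)):
        mask = labels == c
        ax.scatter(coords[mask, 0], coords[mask, 1], s=2, linewidths=0,
                   color=_color(i), label=f"cluster {c}")
    ax.set_xlabel("UMAP1")
    ax.set_ylabel("UMAP2")
    ax.legend(markerscale=4, fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def plot_umap_by_batch(cell_meta: pd.DataFrame, out_path: str | Path) -> Path:
    batches = cell_meta["pool_id"].unique()
    fig, axes = plt.subplots(1, len(batches), figsize=(4 * len(batches), 4), squeeze=False)
    coords = cell_meta[["umap1", "umap2"]].to_numpy()
    for ax, batch in zip(axes[0], batches):
        mask = (cell_meta["pool_id"] == batch).to_numpy()
        _umap_scatter(ax, coords[~mask], "#DDDDDD")
        _umap_scatter(ax, coords[mask], _PALETTE[4])
        ax.set_title(str(batch))
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def plot_feature_umaps(
    cell_meta: pd.DataFrame, expr: np.ndarray, channels: list[str], out_path: str | Path
) -> Path:
    """Per-marker intensity over the embedding."""
    n = len(channels)
    ncol = min(4, n)
    nrow = -(-n // ncol)
    coords = cell_meta[["umap1", "umap2"]].to_numpy()
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.6 * nrow), squeeze=False)
    for i, ch in enumerate(channels):
        ax = axes[i // ncol][i % ncol]
        sc = ax.scatter(coords[:, 0], coords[:, 1], s=2, c=expr[:, i],
                        cmap="viridis", linewidths=0)
        ax.set_title(ch, fontsize=8)
        fig.colorbar(sc, ax=ax, shrink=0.8)
    for j in range(n, nrow * ncol):
        axes[j // ncol][j % ncol].axis("off")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return Path(out_path)


def plot_cluster_dispersion(cell_meta: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Per-cluster UMAP highlight + per-file histogram (dispersion QC)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coords = cell_meta[["umap1", "umap2"]].to_numpy()
    labels = cell_meta["cluster"].to_numpy()
    written = []
    for c in np.unique(labels):
        mask = labels == c
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
        _umap_scatter(ax1, coords[~mask], "#DDDDDD")
        _umap_scatter(ax1, coords[mask], _PALETTE[5])
        ax1.set_title(f"cluster {c} (n={mask.sum()})")
        per_file = cell_meta.loc[mask, "file_name"].value_counts()
        ax2.bar(range(len(per_file)), per_file.values, color=_PALETTE[1])
        ax2.set_xticks(range(len(per_file)))
        ax2.set_xticklabels(per_file.index, rotation=90, fontsize=6)
        ax2.set_ylabel("events")
        fig.tight_layout()
        path = out_dir / f"cluster_{c}_dispersion.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written


def plot_heatmap(
    matrix: pd.DataFrame, out_path: str | Path, title: str = "", cmap: str = "viridis"
) -> Path:
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * matrix.shape[1] + 2), max(3, 0.3 * matrix.shape[0] + 1.5))
    )
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap=cmap)
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index, fontsize=6)
    ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)
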