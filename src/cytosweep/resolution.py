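"""Cluster-resolution selection by Davies-Bouldin sweeps over SOM grids.

The Davies-Bouldin index (DBI) scores a clustering as the mean, over
clusters, of the worst-case ratio ``(S_i + S_j) / M_ij`` where ``S_i`` is the
mean Euclidean distance of cluster-i events to their centroid and ``M_ij``
the distance between centroids — lower means tighter, better-separated
clusters. Sweeping a series of grid sizes and plotting cluster count against
DBI lets the analyst pick a resolution; the pipeline pauses after the sweep
for exactly that choice, with automatic global-minimum / local-minimum
selection available for scripted runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .celltable import CellTable
from .config import SomParams, marker_channels
from .som import assign_bmu, train_som

__all__ = [
    "davies_bouldin_index",
    "SweepResult",
    "grid_sweep",
    "select_grid",
    "default_grid_sizes",
    "read_grid_sizes",
]

DEFAULT_GRIDS: list[tuple[int, int]] = [
    (2, 2), (2, 3), (2, 4), (3, 3), (3, 4), (4, 4),
    (4, 5), (5, 5), (5, 6), (6, 6), (7, 7), (8, 8),
]


def davies_bouldin_index(X: np.ndarray, labels: np.ndarray) -> float:
    """DBI over the non-empty clusters; raises if fewer than two exist."""
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("DBI undefined: fewer than 2 non-empty clusters")
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in ids])
    scatter = np.array(
        [np.linalg.norm(X[labels == c] - centroids[i], axis=1).mean() for i, c in enumerate(ids)]
    )
    M = cdist(centroids, centroids)
    K = len(ids)
    ratios = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            if i != j:
                ratios[i, j] = (scatter[i] + scatter[j]) / M[i, j]
    return float(ratios.max(axis=1).mean())


@dataclass
class SweepResult:
    table: pd.DataFrame  # xdim, ydim, n_clusters_total, n_clusters_nonempty, dbi, seed, failed

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SweepResult":
        return cls(table=pd.read_csv(path))


def grid_sweep(
    table: CellTable,
    markers: pd.DataFrame,
    grid_sizes: list[tuple[int, int]],
    som_params: SomParams | None = None,
) -> SweepResult:
    """Train one SOM per grid size and score each clustering with the DBI.

    Each grid gets a deterministic per-grid seed derived from the configured
    seed, so the sweep is reproducible and grids are independent. A failing
    grid is recorded with a failure flag; the sweep continues.
    """
    if not grid_sizes:
        raise ValueError("grid list is empty")
    som_params = som_params or SomParams()
    X = table.expression(marker_channels(markers, "clustering"))
    rows = []
    seeds = np.random.SeedSequence(som_params.seed).generate_state(len(grid_sizes)) % (2**31)
    for (xdim, ydim), grid_seed in zip(grid_sizes, seeds):
        row = {
            "xdim": xdim, "ydim": ydim,
            "n_clusters_total": xdim * ydim,
            "n_clusters_nonempty": np.nan, "dbi": np.nan,
            "seed": int(grid_seed), "failed": False,
        }
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = train_som(
                    X, xdim, ydim,
                    rlen=som_params.rlen,
                    alpha_start=som_params.alpha_start,
                    alpha_end=som_params.alpha_end,
                    seed=int(grid_seed),
                )
            assignment = assign_bmu(model, X)
            row["n_clusters_nonempty"] = len(np.unique(assignment.labels))
            row["dbi"] = davies_bouldin_index(X, assignment.labels)
        except Exception as exc:  # record and continue
            warnings.warn(f"grid {xdim}x{ydim} failed: {exc}")
            row["failed"] = True
        rows.append(row)
    return SweepResult(table=pd.DataFrame(rows))


def select_grid(
    sweep: SweepResult,
    mode: str = "manual",
    choice: tuple[int, int] | None = None,
) -> tuple[int, int]:
    """Pick a grid from a sweep.

    ``global_min`` takes the smallest DBI (ties: fewest clusters, then lowest
    xdim); ``local_min`` takes the first grid, in ascending cluster-count
    order, whose DBI is below both neighbours, falling back to the global
    minimum with a warning when the sequence is monotone; ``manual`` echoes
    the user's choice, which must be present in the sweep.
    """
    df = sweep.table
    ok = df[(~df["failed"]) & df["dbi"].notna()].copy()
    if len(ok) == 0:
        raise ValueError("sweep contains no scored grids")
    if mode == "manual":
        if choice is None:
            raise ValueError("manual selection requires a grid choice")
        hit = df[(df["xdim"] == choice[0]) & (df["ydim"] == choice[1])]
        if len(hit) == 0:
            raise ValueError(f"grid {choice} not present in the sweep")
        return (int(choice[0]), int(choice[1]))
    if mode == "global_min":
        ok = ok.sort_values(["dbi", "n_clusters_total", "xdim"], kind="mergesort")
        top = ok.iloc[0]
        return (int(top["xdim"]), int(top["ydim"]))
    if mode == "local_min":
        ok = ok.sort_values(["n_clusters_total", "xdim"], kind="mergesort").reset_index(drop=True)
        dbi = ok["dbi"].to_numpy()
        for i in range(1, len(dbi) - 1):
            if dbi[i] < dbi[i - 1] and dbi[i] < dbi[i + 1]:
                return (int(ok.loc[i, "xdim"]), int(ok.loc[i, "ydim"]))
        warnings.warn("no interior local minimum in the DBI sequence; using the global minimum")
        return select_grid(SweepResult(table=ok), mode="global_min")
    raise ValueError(f"unknown selection mode {mode!r}")


def default_grid_sizes() -> list[tuple[int, int]]:
    return list(DEFAULT_GRIDS)


def read_grid_sizes(path: str | Path) -> list[tuple[int, int]]:
    df = pd.read_csv(path)
    for col in ("xdim", "ydim"):
        if col not in df.columns:
            raise ValueError(f"grid sizes file is missing column {col!r}")
    return [(int(r.xdim), int(r.ydim)) for r in df.itertuples()]
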