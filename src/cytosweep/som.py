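"""Self-organizing-map clustering on an xdim x ydim node grid.

Each grid node carries a prototype vector in marker space; after training,
every event is assigned to its best-matching unit (BMU), so the grid size
fixes the cluster count (a 6x6 grid defines 36 clusters, whether or not
every node ends up owning events). Training is the classic online
algorithm: prototypes are initialised from a seeded uniform sample of data
rows, then over ``rlen`` passes each event pulls its BMU and the grid
neighbours within the current radius toward itself, with learning rate and
radius decaying linearly. A bubble (threshold) neighbourhood is used and the
starting radius is the 0.67 quantile of node-to-node grid distances,
shrinking to zero — the defaults common for cytometry SOMs.

Optional metaclustering merges nodes into ``nClus`` groups by average-linkage
hierarchical clustering of the prototype vectors, which keeps the merge
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

__all__ = ["SOMModel", "ClusterAssignment", "train_som", "assign_bmu", "metacluster_codes"]


@dataclass
class SOMModel:
    xdim: int
    ydim: int
    codebook: np.ndarray  # (xdim*ydim) x markers
    node_grid_coords: np.ndarray  # (xdim*ydim) x 2, (col, row)
    training_params: dict = field(default_factory=dict)
    channels: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.xdim * self.ydim


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-event cluster id in 1..C
    C: int
    backend: str  # "som" | "som_meta" | "clara"
    meta_map: np.ndarray | None = None  # node (0-based) -> metacluster id (1-based)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) and (self.labels.min() < 1 or self.labels.max() > self.C):
            raise ValueError(f"labels must lie in 1..{self.C}")


@njit(cache=True)
def _som_online(X, codebook, grid_dist, order, alpha_start, alpha_end, radius_start):
    n, m = X.shape
    n_nodes = codebook.shape[0]
    rlen = order.shape[0]
    total = rlen * n
    step = 0
    for p in range(rlen):
        for t in range(n):
            i = order[p, t]
            frac = step / total
            alpha = alpha_start - (alpha_start - alpha_end) * frac
            radius = radius_start * (1.0 - frac)
            # best-matching unit, ties to the lowest node index
            best = 0
            best_d = np.inf
            for j in range(n_nodes):
                d = 0.0
                for c in range(m):
                    diff = X[i, c] - codebook[j, c]
                    d += diff * diff
                if d < best_d:
                    best_d = d
                    best = j
            for j in range(n_nodes):
                if grid_dist[best, j] <= radius:
                    for c in range(m):
                        codebook[j, c] += alpha * (X[i, c] - codebook[j, c])
            step += 1
    return codebook


def _grid_coords(xdim: int, ydim: int) -> np.ndarray:
    nodes = np.arange(xdim * ydim)
    return np.column_stack([nodes % xdim, nodes // xdim]).astype(np.float64)


def train_som(
    X: np.ndarray,
    xdim: int,
    ydim: int,
    *,
    rlen: int = 10,
    alpha_start: float = 0.05,
    alpha_end: float = 0.01,
    seed: int = 42,
    channels: list[str] | None = None,
) -> SOMModel:
    """Train the online SOM; deterministic for a fixed seed."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError(f"training matrix must be 2-D and non-empty, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("training matrix contains non-finite values")
    n, _m = X.shape
    n_nodes = xdim * ydim
    if n_nodes > n:
        import warnings

        warnings.warn(
            f"grid has {n_nodes} nodes but only {n} events; some nodes will be empty"
        )
    rng = np.random.default_rng(seed)
    # Seeded uniform sample of data rows, drawn from the distinct rows when
    # enough exist so heavily duplicated events cannot collapse the initial
    # prototypes onto each other.
    uniq = np.unique(X, axis=0)
    pool = uniq if len(uniq) >= n_nodes else X
    init_rows = rng.choice(len(pool), size=n_nodes, replace=n_nodes > len(pool))
    codebook = pool[init_rows].copy()

    coords = _grid_coords(xdim, ydim)
    grid_dist = cdist(coords, coords)
    if n_nodes > 1:
        radius_start = float(np.quantile(grid_dist[grid_dist > 0], 0.67))
    else:
        radius_start = 0.0
    order = np.vstack([rng.permutation(n) for _ in range(rlen)]).astype(np.int64)

    codebook = _som_online(
        X, codebook, grid_dist, order, float(alpha_start), float(alpha_end), radius_start
    )
    return SOMModel(
        xdim=xdim,
        ydim=ydim,
        codebook=np.asarray(codebook),
        node_grid_coords=coords,
        training_params={
            "rlen": rlen,
            "alpha_start": alpha_start,
            "alpha_end": alpha_end,
            "radius_start": radius_start,
            "seed": seed,
        },
        channels=channels,
    )


def assign_bmu(model: SOMModel, X: np.ndarray) -> ClusterAssignment:
    """Label each event with its nearest prototype (1-based node index).

    Equidistant prototypes resolve to the lowest node index. The cluster
    count is the full grid size; nodes owning no events stay valid ids.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != model.codebook.shape[1]:
        raise ValueError(
            f"event matrix has {X.shape[1]} columns but the codebook has "
            f"{model.codebook.shape[1]}"
        )
    d = cdist(X, model.codebook)
    labels = d.argmin(axis=1) + 1  # argmin takes the first (lowest) index on ties
    return ClusterAssignment(labels=labels, C=model.n_nodes, backend="som")


def metacluster_codes(
    model: SOMModel, nClus: int, occupied: np.ndarray | None = None
) -> np.ndarray:
    """Merge grid nodes into ``nClus`` metaclusters (average linkage).

    Returns a node -> metacluster map (1-based metacluster ids, array indexed
    by 0-based node). When an ``occupied`` boolean mask is given, only nodes
    that own events are clustered — prototypes stranded without events carry
    no population signal and would otherwise claim metacluster slots — and
    every empty node is mapped to the group of its nearest occupied
    prototype, so the full grid stays covered. Metacluster ids are renumbered
    by first node occurrence so the map is stable under library version
    changes.
    """
    n_nodes = model.n_nodes
    if not 1 <= nClus <= n_nodes:
        raise ValueError(f"nClus must be in 1..{n_nodes}, got {nClus}")
    if nClus == n_nodes:
        return np.arange(1, n_nodes + 1)
    out = np.empty(n_nodes, dtype=np.int64)
    if nClus == 1:
        out[:] = 1
        return out
    if occupied is not None and occupied.sum() >= nClus:
        occ_idx = np.flatnonzero(occupied)
    else:
        occ_idx = np.arange(n_nodes)
    Z = linkage(model.codebook[occ_idx], method="average", metric="euclidean")
    groups = fcluster(Z, t=nClus, criterion="maxclust")
    out[occ_idx] = groups
    rest = np.setdiff1d(np.arange(n_nodes), occ_idx)
    if len(rest):
        d = cdist(model.codebook[rest], model.codebook[occ_idx])
        out[rest] = groups[d.argmin(axis=1)]
    # renumber in order of first appearance
    remap: dict[int, int] = {}
    final = np.empty(n_nodes, dtype=np.int64)
    for i, g in enumerate(out):
        if g not in remap:
            remap[g] = len(remap) + 1
        final[i] = remap[g]
    return final


def apply_metaclustering(assignment: ClusterAssignment, meta_map: np.ndarray) -> ClusterAssignment:
    """Relabel a node-level assignment with metacluster ids."""
    if assignment.backend != "som":
        raise ValueError("metaclustering applies to SOM node assignments")
    labels = meta_map[assignment.labels - 1]
    return ClusterAssignment(
        labels=labels, C=int(meta_map.max()), backend="som_meta", meta_map=meta_map
    )
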