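"""CLARA (Clustering LARge Applications): k-medoids for big event tables.

PAM (partitioning around medoids) is exact but quadratic in the number of
events, so CLARA runs PAM on several seeded subsamples of size
``min(n, 40 + 2k)`` and keeps the medoid set with the lowest mean
dissimilarity measured against *all* events. The classic BUILD phase greedily
seeds medoids; SWAP then exchanges a medoid with a non-medoid whenever that
lowers total cost, until no exchange helps — the cost is non-increasing by
construction, which is asserted.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .som import ClusterAssignment

__all__ = ["pam", "clara_cluster"]

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock"}


def _pairwise(X: np.ndarray, metric: str) -> np.ndarray:
    return cdist(X, X, metric=_METRICS[metric])


def pam(D: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """PAM on a precomputed dissimilarity matrix.

    Returns (sorted medoid indices, total cost). BUILD then SWAP with
    best-improvement steps; the asserted invariant is that SWAP never
    increases the cost.
    """
    n = D.shape[0]
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points n={n}")

    # BUILD: first medoid minimises total distance; each next medoid
    # maximises the cost reduction it brings.
    medoids = [int(D.sum(axis=1).argmin())]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -1.0
        best = int(gains.argmax())
        medoids.append(best)
        nearest = np.minimum(nearest, D[:, best])

    med = np.array(sorted(medoids))
    cost = D[:, med].min(axis=1).sum()
    while True:
        improved = False
        best_cost = cost
        best_pair = None
        non_med = np.setdiff1d(np.arange(n), med, assume_unique=False)
        for mi in range(k):
            trial = med.copy()
            for h in non_med:
                trial[mi] = h
                c = D[:, trial].min(axis=1).sum()
                if c < best_cost - 1e-12:
                    best_cost = c
                    best_pair = (mi, h)
            trial[mi] = med[mi]
        if best_pair is not None:
            mi, h = best_pair
            med[mi] = h
            med = np.sort(med)
            assert best_cost <= cost + 1e-9, "SWAP increased the cost"
            cost = best_cost
            improved = True
        if not improved:
            break
    return med, float(cost)


def clara_cluster(
    X: np.ndarray,
    k: int,
    metric: str = "euclidean",
    samples: int = 50,
    seed: int = 42,
) -> ClusterAssignment:
    """CLARA over seeded subsamples; best medoid set by full-data cost."""
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the event count n={n}")
    if samples < 1:
        raise ValueError("samples must be >= 1")
    if metric not in _METRICS:
        raise ValueError(f"unsupported metric {metric!r}")

    sampsize = min(n, 40 + 2 * k)
    rng = np.random.default_rng(seed)
    best_medoid_rows: np.ndarray | None = None
    best_score = np.inf
    for _ in range(samples):
        idx = rng.choice(n, size=sampsize, replace=False)
        sub = X[idx]
        D = _pairwise(sub, metric)
        med_local, _cost = pam(D, k)
        medoid_rows = X[idx[med_local]]
        full = cdist(X, medoid_rows, metric=_METRICS[metric])
        score = full.min(axis=1).mean()
        if score < best_score - 1e-12:
            best_score = score
            best_medoid_rows = medoid_rows
        if best_score == 0.0:
            break
    assert best_medoid_rows is not None
    full = cdist(X, best_medoid_rows, metric=_METRICS[metric])
    labels = full.argmin(axis=1) + 1
    out = ClusterAssignment(labels=labels, C=k, backend="clara")
    out.medoids = best_medoid_rows  # attached for inspection
    out.mean_dissimilarity = best_score
    return out
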