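"""Independent brute-force oracles used to cross-check the implementations.

Everything here is written from first principles (pair enumeration,
contingency tables, literal definitions) and deliberately shares no code
with the package.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def dbi_brute_force(X: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index straight from the definition."""
    ids = sorted(set(labels.tolist()))
    assert len(ids) >= 2
    centroids = {}
    scatters = {}
    for c in ids:
        pts = X[labels == c]
        mu = pts.mean(axis=0)
        centroids[c] = mu
        scatters[c] = float(np.mean([math.dist(p, mu) for p in pts]))
    worst = []
    for i in ids:
        ratios = []
        for j in ids:
            if i == j:
                continue
            m = math.dist(centroids[i], centroids[j])
            ratios.append((scatters[i] + scatters[j]) / m)
        worst.append(max(ratios))
    return sum(worst) / len(ids)


def pair_counts(truth, pred) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) over all item pairs."""
    tp = fp = fn = tn = 0
    n = len(truth)
    for i, j in combinations(range(n), 2):
        same_t = truth[i] == truth[j]
        same_p = pred[i] == pred[j]
        if same_t and same_p:
            tp += 1
        elif not same_t and same_p:
            fp += 1
        elif same_t and not same_p:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def ari_brute_force(truth, pred) -> float:
    """Hubert-Arabie adjusted Rand index from the contingency table."""
    t_ids = sorted(set(truth))
    p_ids = sorted(set(pred))
    n = len(truth)
    nij = {(a, b): 0 for a in t_ids for b in p_ids}
    for t, p in zip(truth, pred):
        nij[(t, p)] += 1
    a_i = {a: sum(nij[(a, b)] for b in p_ids) for a in t_ids}
    b_j = {b: sum(nij[(a, b)] for a in t_ids) for b in p_ids}
    sum_ij = sum(math.comb(v, 2) for v in nij.values())
    sum_a = sum(math.comb(v, 2) for v in a_i.values())
    sum_b = sum(math.comb(v, 2) for v in b_j.values())
    expected = sum_a * sum_b / math.comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0  # both partitions trivial in the same way
    return (sum_ij - expected) / (max_index - expected)


def fm_brute_force(truth, pred) -> float:
    tp, fp, fn, _ = pair_counts(truth, pred)
    denom = math.sqrt((tp + fp) * (tp + fn))
    assert denom > 0, "FM undefined"
    return tp / denom


def mi_brute_force(truth, pred) -> float:
    """Mutual information in nats from the joint label distribution."""
    n = len(truth)
    joint: dict[tuple, int] = {}
    pt: dict[object, int] = {}
    pp: dict[object, int] = {}
    for t, p in zip(truth, pred):
        joint[(t, p)] = joint.get((t, p), 0) + 1
        pt[t] = pt.get(t, 0) + 1
        pp[p] = pp.get(p, 0) + 1
    mi = 0.0
    for (t, p), c in joint.items():
        pij = c / n
        mi += pij * math.log(pij / ((pt[t] / n) * (pp[p] / n)))
    return mi


def entropy(labels) -> float:
    n = len(labels)
    counts: dict[object, int] = {}
    for x in labels:
        counts[x] = counts.get(x, 0) + 1
    return -sum((c / n) * math.log(c / n) for c in counts.values())
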