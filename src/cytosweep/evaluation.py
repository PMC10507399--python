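"""Agreement between cluster-derived annotations and gated ground truth.

The protocol: restrict to barcodes present in both label tables, repeatedly
subsample 10,000 cells without replacement, compute accuracy (exact label
match — both sides carry expert cell-type strings, so no cluster matching is
applied), the adjusted Rand index, the Fowlkes-Mallows index and mutual
information (in nats by default), and average over 10 repeats with seeds
derived from one master seed.

Also provides the tetramer positivity gate: an event is positive when its
raw intensity is at least three standard deviations above the mean of the
supplied intensities (sample sd, ddof=1, configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    adjusted_rand_score,
    fowlkes_mallows_score,
    mutual_info_score,
)

__all__ = [
    "accuracy",
    "adjusted_rand_index",
    "fowlkes_mallows",
    "mutual_information",
    "ConcordanceReport",
    "concordance_report",
    "tetramer_gate",
]


def _align(truth: pd.DataFrame, pred: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Labels over the intersection of barcodes, truth order."""
    for name, df in (("truth", truth), ("pred", pred)):
        for col in ("cell_id", "label"):
            if col not in df.columns:
                raise ValueError(f"{name} table lacks a {col!r} column")
    merged = truth[["cell_id", "label"]].merge(
        pred[["cell_id", "label"]], on="cell_id", suffixes=("_truth", "_pred")
    )
    if len(merged) == 0:
        raise ValueError("no shared cell barcodes between truth and prediction")
    return merged["label_truth"].to_numpy(), merged["label_pred"].to_numpy()


def accuracy(truth: pd.DataFrame, pred: pd.DataFrame) -> float:
    """Exact string-match fraction over shared barcodes."""
    t, p = _align(truth, pred)
    return float((t == p).mean())


def adjusted_rand_index(truth, pred) -> float:
    """Chance-corrected pair-counting agreement (Hubert-Arabie)."""
    truth = np.asarray(truth)
    if len(truth) < 2:
        raise ValueError("ARI needs at least 2 items")
    return float(adjusted_rand_score(truth, np.asarray(pred)))


def fowlkes_mallows(truth, pred) -> float:
    """TP / sqrt((TP+FP)(TP+FN)) over same-cluster pairs."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if len(truth) < 2:
        raise ValueError("Fowlkes-Mallows needs at least 2 items")
    if len(np.unique(truth)) == len(truth) or len(np.unique(pred)) == len(pred):
        raise ValueError("Fowlkes-Mallows undefined: a partition has no same-cluster pairs")
    return float(fowlkes_mallows_score(truth, pred))


def mutual_information(truth, pred) -> float:
    """Mutual information of the two partitions, in nats."""
    return float(mutual_info_score(np.asarray(truth), np.asarray(pred)))


@dataclass
class ConcordanceReport:
    per_repeat: pd.DataFrame  # repeat, seed, accuracy, ari, fowlkes_mallows, mutual_information
    n_per_repeat: int
    n_repeats: int
    seeds: list[int] = field(default_factory=list)

    @property
    def means(self) -> pd.Series:
        return self.per_repeat[
            ["accuracy", "adjusted_rand_index", "fowlkes_mallows", "mutual_information"]
        ].mean()

    def to_csv(self, path) -> None:
        out = self.per_repeat.copy()
        mean_row = self.means
        mean_row["repeat"] = "mean"
        out = pd.concat([out, mean_row.to_frame().T], ignore_index=True)
        out.to_csv(path, index=False)


def concordance_report(
    truth: pd.DataFrame,
    pred: pd.DataFrame,
    n_per_repeat: int = 10_000,
    n_repeats: int = 10,
    seed: int = 42,
) -> ConcordanceReport:
    """Repeated-subsample four-metric concordance between two label tables."""
    t, p = _align(truth, pred)
    n = len(t)
    if n < n_per_repeat:
        warnings.warn(
            f"only {n} shared barcodes; subsample capped at {n} (requested {n_per_repeat})"
        )
        n_per_repeat = n
    seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)]
    rows = []
    for r, s in enumerate(seeds, start=1):
        rng = np.random.default_rng(s)
        idx = rng.choice(n, size=n_per_repeat, replace=False)
        ts, ps = t[idx], p[idx]
        rows.append(
            {
                "repeat": r,
                "seed": s,
                "accuracy": float((ts == ps).mean()),
                "adjusted_rand_index": adjusted_rand_index(ts, ps),
                "fowlkes_mallows": fowlkes_mallows(ts, ps),
                "mutual_information": mutual_information(ts, ps),
            }
        )
    return ConcordanceReport(
        per_repeat=pd.DataFrame(rows),
        n_per_repeat=n_per_repeat,
        n_repeats=n_repeats,
        seeds=seeds,
    )


def tetramer_gate(intensities: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Positive iff intensity >= mean + 3 sd of the supplied intensities."""
    x = np.asarray(intensities, dtype=np.float64)
    if x.size < 2:
        raise ValueError("tetramer gate needs at least 2 events")
    sd = x.std(ddof=ddof)
    if sd == 0:
        warnings.warn("zero variance: no events can exceed mean + 3 sd")
        return x > x.mean()
    return x >= x.mean() + 3.0 * sd
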