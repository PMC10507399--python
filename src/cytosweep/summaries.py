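"""Cluster-level summary matrices.

After clustering, three tables drive annotation and QC: per-file cluster
frequencies (raw counts and within-file proportions), per-batch composition,
and median arcsinh-transformed expression per cluster over *all* markers —
unscaled, so heatmap values stay comparable across markers. A row-scaled
variant ((x - row mean) / row sd, constant rows mapping to 0) is provided
for shape-focused heatmaps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .celltable import CellTable
from .som import ClusterAssignment

__all__ = [
    "cluster_frequencies",
    "batch_composition",
    "cluster_median_expression",
    "row_scale",
    "summarize",
]


def _cluster_columns(C: int) -> list[str]:
    return [f"cluster_{c}" for c in range(1, C + 1)]


def _crosstab(groups: pd.Series, labels: np.ndarray, C: int) -> pd.DataFrame:
    counts = pd.crosstab(groups, pd.Series(labels, index=groups.index, name="cluster"))
    counts = counts.reindex(columns=range(1, C + 1), fill_value=0)
    counts.columns = _cluster_columns(C)
    return counts


def cluster_frequencies(
    table: CellTable, assignment: ClusterAssignment
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-file cluster counts and within-file proportions.

    Every cluster id 1..C appears as a column, empty clusters included, so
    matrices from different runs of the same grid stay comparable.
    """
    if len(assignment.labels) != len(table):
        raise ValueError("assignment is not aligned to the table")
    freq_raw = _crosstab(table.cell_meta["file_name"], assignment.labels, assignment.C)
    totals = freq_raw.sum(axis=1)
    freq_norm = freq_raw.div(totals.where(totals > 0, 1), axis=0)
    return freq_raw, freq_norm


def batch_composition(table: CellTable, assignment: ClusterAssignment) -> pd.DataFrame:
    """Batch (pool_id) x cluster event counts."""
    return _crosstab(table.cell_meta["pool_id"], assignment.labels, assignment.C)


def cluster_median_expression(
    table: CellTable,
    assignment: ClusterAssignment,
    markers: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Median transformed expression per cluster over all markers, unscaled.

    Clusters without events yield all-NaN rows rather than being dropped.
    """
    X = table.expression()
    labels = assignment.labels
    rows = []
    for c in range(1, assignment.C + 1):
        mask = labels == c
        if mask.any():
            rows.append(np.median(X[mask], axis=0))
        else:
            rows.append(np.full(X.shape[1], np.nan))
    return pd.DataFrame(rows, index=_cluster_columns(assignment.C), columns=table.channels)


def row_scale(df: pd.DataFrame) -> pd.DataFrame:
    """(x - row mean) / row sd per row; rows with zero sd map to 0."""
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    scaled = df.sub(mean, axis=0).div(sd.where(sd > 0, 1), axis=0)
    scaled[sd == 0] = 0.0
    return scaled


def summarize(table: CellTable, assignment: ClusterAssignment) -> dict[str, pd.DataFrame]:
    """All summary matrices in one pass (frequencies, batch, medians)."""
    freq_raw, freq_norm = cluster_frequencies(table, assignment)
    return {
        "freq_raw": freq_raw,
        "freq_norm": freq_norm,
        "batch_comp": batch_composition(table, assignment),
        "median_expr": cluster_median_expression(table, assignment),
    }
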