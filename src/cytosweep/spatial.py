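"""Spatial context for imaging-derived clusters.

Joins cluster labels to cell centroids and region annotations (stroma /
tumor / other, drawn upstream on the tissue image) and quantifies where each
cluster lives: per-region cluster composition and the log2 ratio of a
cluster's stromal frequency over its tumor frequency. Clusters absent from
either compartment are flagged undefined rather than imputed.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .som import ClusterAssignment

__all__ = ["region_frequencies", "log2_enrichment", "export_overlay"]

REGIONS = ("stroma", "tumor", "other")


def _joined(assignment: ClusterAssignment, regions: pd.DataFrame, cell_ids) -> pd.DataFrame:
    labels = pd.DataFrame({"cell_id": cell_ids, "cluster": assignment.labels})
    merged = labels.merge(regions, on="cell_id")
    if len(merged) == 0:
        raise ValueError("no shared barcodes between cluster labels and region table")
    return merged


def region_frequencies(
    assignment: ClusterAssignment, regions: pd.DataFrame, cell_ids
) -> pd.DataFrame:
    """Cluster x region matrix of within-region proportions.

    ``freq[c, r]`` is the fraction of region-r cells that belong to cluster
    c, so each populated region column sums to 1. Regions with no cells are
    dropped with a warning.
    """
    merged = _joined(assignment, regions, cell_ids)
    counts = pd.crosstab(merged["cluster"], merged["region"], dropna=False)
    counts = counts.reindex(index=range(1, assignment.C + 1), fill_value=0)
    present = [r for r in counts.columns if counts[r].sum() > 0]
    dropped = [r for r in counts.columns if r not in present]
    if dropped:
        warnings.warn(f"region(s) with zero cells dropped: {dropped}")
    counts = counts[present]
    freq = counts.div(counts.sum(axis=0), axis=1)
    freq.index = [f"cluster_{c}" for c in freq.index]
    return freq


def log2_enrichment(freq: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster log2(stroma frequency / tumor frequency).

    Clusters with zero frequency in either compartment get NaN and an
    ``undefined`` flag instead of a pseudocount.
    """
    for col in ("stroma", "tumor"):
        if col not in freq.columns:
            raise ValueError(f"frequency matrix lacks a {col!r} column")
    s = freq["stroma"].to_numpy(dtype=np.float64)
    t = freq["tumor"].to_numpy(dtype=np.float64)
    defined = (s > 0) & (t > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.where(defined, np.log2(np.where(defined, s, 1) / np.where(defined, t, 1)), np.nan)
    return pd.DataFrame(
        {"log2_stroma_over_tumor": lfc, "undefined": ~defined}, index=freq.index
    )


def export_overlay(
    assignment: ClusterAssignment,
    regions: pd.DataFrame,
    cell_ids,
    out_path: str | Path | None = None,
    cluster_filter: set[int] | None = None,
) -> pd.DataFrame:
    """Per-cell {cell_id, x, y, cluster} table for image overlays.

    ``cluster_filter`` restricts the export to the chosen clusters (e.g. a
    single cluster of interest); an empty set yields only the header.
    """
    for col in ("x", "y"):
        if col not in regions.columns:
            raise ValueError(f"region table lacks coordinate column {col!r}")
    merged = _joined(assignment, regions, cell_ids)
    out = merged[["cell_id", "x", "y", "cluster"]]
    if cluster_filter is not None:
        out = out[out["cluster"].isin(cluster_filter)]
    if out_path is not None:
        out.to_csv(out_path, index=False)
    return out.reset_index(drop=True)
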