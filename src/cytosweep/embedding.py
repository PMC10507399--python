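"""2-D neighbourhood-preserving embedding of the transformed matrix.

UMAP is computed on the markers flagged ``used_for_UMAP`` only, and the
coordinates are attached to the cell metadata as ``umap1``/``umap2``. The
embedding is strictly a visualisation aid: clustering operates in marker
space and never consumes these coordinates. Deterministic for a fixed seed
(umap-learn runs single-threaded when a random_state is given).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .celltable import CellTable
from .config import UmapParams, marker_channels

__all__ = ["EmbeddingResult", "compute_embedding"]


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # events x 2
    params_used: UmapParams


def compute_embedding(
    table: CellTable, markers: pd.DataFrame, params: UmapParams | None = None
) -> EmbeddingResult:
    """Embed the transformed matrix on UMAP markers; attach umap1/umap2."""
    import umap  # deferred: numba compilation on first import is slow

    params = params or UmapParams()
    channels = marker_channels(markers, "umap")
    if not channels:
        raise ValueError("no markers are flagged used_for_UMAP")
    X = table.expression(channels)
    if len(X) < params.n_neighbors + 1:
        raise ValueError(
            f"{len(X)} events is fewer than n_neighbors+1 ({params.n_neighbors + 1}); "
            "lower n_neighbors"
        )
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=params.n_neighbors,
        min_dist=params.min_dist,
        spread=params.spread,
        learning_rate=params.learning_rate,
        init=params.init,
        random_state=params.seed,
    )
    coords = np.asarray(reducer.fit_transform(X), dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("embedding produced non-finite coordinates")
    table.cell_meta["umap1"] = coords[:, 0]
    table.cell_meta["umap2"] = coords[:, 1]
    return EmbeddingResult(coords=coords, params_used=params)
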