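"""Variance-stabilising arcsinh transform.

Cytometry intensities are transformed as ``asinh(x / cofactor)``. The
cofactor sets where the transform bends from near-linear to logarithmic:
around 5 for mass cytometry counts, of order 150-6000 for fluorescence
intensities. One global cofactor applies per run; negative inputs (possible
after compensation) pass through unchanged since asinh is defined on all
reals.
"""

from __future__ import annotations

import numpy as np

from .celltable import CellTable

__all__ = ["arcsinh_transform", "apply_transform"]


def arcsinh_transform(raw: np.ndarray, cofactor: float) -> np.ndarray:
    """Elementwise ``asinh(raw / cofactor)``; strictly increasing in raw."""
    if cofactor <= 0:
        raise ValueError(f"arcsinh cofactor must be > 0, got {cofactor}")
    return np.arcsinh(np.asarray(raw, dtype=np.float64) / cofactor)


def apply_transform(table: CellTable, cofactor: float) -> CellTable:
    """Populate the transformed matrix of a CellTable from its raw matrix."""
    if table.raw_expr is None:
        raise ValueError("table has no raw expression matrix to transform")
    table.trans_expr = arcsinh_transform(table.raw_expr, cofactor)
    table.cofactor = float(cofactor)
    return table
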