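"""Data intake: FCS directories or pre-computed matrices into a CellTable.

Events are concatenated in file-metadata row order; per-event metadata is
copied from the owning file's record; channels follow the marker-metadata
order. Cell barcodes combine the sample identifier (the FCS basename
without extension) with the 1-based event index within that file,
``<sample_id>_<cell_id>``, so events remain traceable across subsetting
and evaluation against external label tables.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .celltable import CellTable
from .config import marker_channels
from .fcsio import read_fcs

__all__ = [
    "load_fcs_directory",
    "load_matrix",
    "assign_cell_ids",
    "remove_controls",
    "subsample_per_file",
]


def load_fcs_directory(
    fcs_dir: str | Path,
    files: pd.DataFrame,
    markers: pd.DataFrame,
) -> CellTable:
    """Read every file in the file-metadata table into one raw CellTable."""
    fcs_dir = Path(fcs_dir)
    channels = marker_channels(markers)
    blocks: list[np.ndarray] = []
    meta_rows: list[pd.DataFrame] = []
    for _, rec in files.iterrows():
        path = fcs_dir / rec["file_name"]
        if not path.exists():
            raise FileNotFoundError(f"FCS file not found: {path}")
        data, _text = read_fcs(path)
        missing = [c for c in channels if c not in data.columns]
        if missing:
            raise ValueError(
                f"channel not found: {missing} absent from {rec['file_name']}"
            )
        if len(data) == 0:
            warnings.warn(f"{rec['file_name']}: empty FCS file, contributes no events")
            continue
        blocks.append(data[channels].to_numpy(dtype=np.float64))
        meta = pd.DataFrame(
            {
                "file_name": rec["file_name"],
                "donor_id": rec["donor_id"],
                "pool_id": rec["pool_id"],
                "control_sample": bool(rec["control_sample"]),
            },
            index=range(len(data)),
        )
        meta_rows.append(meta)
    if blocks:
        raw = np.vstack(blocks)
        cell_meta = pd.concat(meta_rows, ignore_index=True)
    else:
        raw = np.empty((0, len(channels)))
        cell_meta = pd.DataFrame(columns=["file_name", "donor_id", "pool_id", "control_sample"])
    table = CellTable(channels=channels, cell_meta=cell_meta, raw_expr=raw)
    return assign_cell_ids(table)


def load_matrix(
    matrix_path: str | Path,
    cell_meta_path: str | Path | None,
    markers: pd.DataFrame,
    already_transformed: bool = False,
) -> CellTable:
    """Intake a cells x markers CSV instead of an FCS directory.

    With ``already_transformed`` the values are stored directly as the
    transformed matrix (the imaging ``trans_exp.csv`` route) and no raw
    matrix is kept; otherwise they are treated as raw counts.
    """
    mat = pd.read_csv(matrix_path)
    if len(mat) == 0:
        raise ValueError(f"empty input: {matrix_path} has no rows")
    channels = marker_channels(markers)
    missing = [c for c in channels if c not in mat.columns]
    if missing:
        raise ValueError(f"matrix is missing marker column(s): {missing}")
    extra = [c for c in mat.columns if c not in channels]
    if extra:
        warnings.warn(f"matrix: ignoring extra column(s) {extra}")
    values = mat[channels].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(~mat[channels].map(np.isreal).to_numpy())
        r, c = bad[0]
        raise ValueError(f"non-numeric value at row {r}, column {channels[c]}")
    values = values.astype(np.float64)

    if cell_meta_path is not None:
        meta = pd.read_csv(cell_meta_path)
        if len(meta) != len(mat):
            raise ValueError(
                f"alignment error: matrix has {len(mat)} rows but cell metadata "
                f"has {len(meta)}"
            )
    else:
        meta = pd.DataFrame(index=range(len(mat)))
    if "file_name" not in meta.columns:
        meta = meta.copy()
        meta["file_name"] = Path(matrix_path).stem
    for col, default in (("donor_id", "unknown"), ("pool_id", "unknown"), ("control_sample", False)):
        if col not in meta.columns:
            meta[col] = default

    table = CellTable(
        channels=channels,
        cell_meta=meta,
        raw_expr=None if already_transformed else values,
        trans_expr=values if already_transformed else None,
    )
    if "cell_id" not in meta.columns:
        table = assign_cell_ids(table)
    return table


def assign_cell_ids(table: CellTable) -> CellTable:
    """Attach ``<sample_id>_<cell_id>`` barcodes (1-based index per file)."""
    meta = table.cell_meta.copy()
    if "file_name" not in meta.columns:
        raise ValueError("cell metadata lacks a file_name column")
    sample_ids = meta["file_name"].astype(str).str.replace(r"\.fcs$", "", regex=True)
    index_within = meta.groupby(sample_ids, sort=False).cumcount() + 1
    meta["cell_id"] = sample_ids + "_" + index_within.astype(str)
    if meta["cell_id"].duplicated().any():
        dupes = meta.loc[meta["cell_id"].duplicated(), "cell_id"].head().tolist()
        raise ValueError(f"duplicate cell barcodes generated (e.g. {dupes}); "
                         "is a file listed twice in the metadata?")
    cols = ["cell_id"] + [c for c in meta.columns if c != "cell_id"]
    table.cell_meta = meta[cols]
    return table


def remove_controls(table: CellTable) -> CellTable:
    """Drop events whose source file is flagged as a control sample."""
    keep = ~table.cell_meta["control_sample"].astype(bool).to_numpy()
    if not keep.any():
        warnings.warn("remove_controls: all events were controls; table is now empty")
    return table.take(np.flatnonzero(keep))


def subsample_per_file(table: CellTable, n_per_file: int, seed: int) -> CellTable:
    """Uniform without-replacement draw of up to ``n_per_file`` events per file.

    Files with fewer events than requested keep everything. Reproducible for
    a fixed seed; relative event order within each file is preserved.
    """
    if n_per_file < 1:
        raise ValueError(f"n_per_file must be >= 1, got {n_per_file}")
    rng = np.random.default_rng(seed)
    keep_positions: list[np.ndarray] = []
    for _name, group in table.cell_meta.groupby("file_name", sort=False):
        pos = group.index.to_numpy()
        if len(pos) > n_per_file:
            pos = np.sort(rng.choice(pos, size=n_per_file, replace=False))
        keep_positions.append(pos)
    order = np.concatenate(keep_positions) if keep_positions else np.empty(0, dtype=int)
    return table.take(order)
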