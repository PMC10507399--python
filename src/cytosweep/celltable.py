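"""The per-event table every stage reads and writes.

A :class:`CellTable` joins the raw and arcsinh-transformed expression
matrices (events x channels) to per-event metadata (source file, donor,
batch, control flag, and — as the pipeline progresses — embedding
coordinates, cluster assignment, ground-truth label). Checkpoints are
directories holding the expression blocks as ``.npy`` plus the metadata and
channel list as CSV/JSON, so any stage can be resumed or inspected with
standard tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CellTable"]


@dataclass
class CellTable:
    channels: list[str]
    cell_meta: pd.DataFrame
    raw_expr: np.ndarray | None = None
    trans_expr: np.ndarray | None = None
    cofactor: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.cell_meta)
        for name in ("raw_expr", "trans_expr"):
            mat = getattr(self, name)
            if mat is not None:
                mat = np.asarray(mat, dtype=np.float64)
                if mat.shape != (n, len(self.channels)):
                    raise ValueError(
                        f"{name} shape {mat.shape} does not match "
                        f"{n} events x {len(self.channels)} channels"
                    )
                setattr(self, name, mat)
        self.cell_meta = self.cell_meta.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.cell_meta)

    @property
    def n_events(self) -> int:
        return len(self.cell_meta)

    def has_column(self, name: str) -> bool:
        return name in self.cell_meta.columns

    def expression(self, channels: list[str] | None = None, *, transformed: bool = True) -> np.ndarray:
        """Expression sub-matrix for the given channels (default: all)."""
        mat = self.trans_expr if transformed else self.raw_expr
        if mat is None:
            kind = "transformed" if transformed else "raw"
            raise ValueError(f"{kind} expression matrix is not available")
        if channels is None:
            return mat
        idx = [self.channels.index(c) for c in channels]
        return mat[:, idx]

    def take(self, positions: np.ndarray) -> "CellTable":
        """Row subset in the given order (positional indices)."""
        positions = np.asarray(positions)
        return CellTable(
            channels=list(self.channels),
            cell_meta=self.cell_meta.iloc[positions].reset_index(drop=True),
            raw_expr=None if self.raw_expr is None else self.raw_expr[positions],
            trans_expr=None if self.trans_expr is None else self.trans_expr[positions],
            cofactor=self.cofactor,
            extras=dict(self.extras),
        )

    # --- checkpoint container -------------------------------------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cell_meta.to_csv(directory / "cell_meta.csv", index=False)
        manifest = {
            "channels": self.channels,
            "cofactor": self.cofactor,
            "n_events": self.n_events,
            "extras": _jsonable(self.extras),
        }
        (directory / "table.json").write_text(json.dumps(manifest, indent=2))
        if self.raw_expr is not None:
            np.save(directory / "raw_expr.npy", self.raw_expr)
        if self.trans_expr is not None:
            np.save(directory / "trans_expr.npy", self.trans_expr)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "CellTable":
        directory = Path(directory)
        manifest = json.loads((directory / "table.json").read_text())
        meta = pd.read_csv(directory / "cell_meta.csv")
        raw = trans = None
        if (directory / "raw_expr.npy").exists():
            raw = np.load(directory / "raw_expr.npy")
        if (directory / "trans_expr.npy").exists():
            trans = np.load(directory / "trans_expr.npy")
        return cls(
            channels=manifest["channels"],
            cell_meta=meta,
            raw_expr=raw,
            trans_expr=trans,
            cofactor=manifest.get("cofactor"),
            extras=manifest.get("extras", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj
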