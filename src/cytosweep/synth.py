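"""Seeded synthetic multi-sample cytometry datasets with known structure.

Populations are Gaussian on the arcsinh scale: each population has a
per-marker signature mean and spread, so after the pipeline's forward
transform the planted structure is analytically controllable. Raw counts are
recovered as ``cofactor * sinh(value)`` truncated at zero (counts are
non-negative). The generator emulates the layout of a real run — several
FCS files across batches with an additive per-batch arcsinh-scale shift,
control files replicated across batches, and per-cell ground-truth labels —
and can emit the exact on-disk file set a run needs (FCS directory, the two
metadata CSVs, config.yml, a gated landmark directory with one file per
population, and a truth-label table).

The default design plants five immune-like populations (CD4 T, CD8 T, B,
monocyte, NK signatures over ten markers) with high/low signature levels of
3.5/0.5 and spread 0.3 arcsinh units — a 10-sd separation, the
well-separated regime in which cluster-recovery guarantees are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .celltable import CellTable
from .fcsio import write_fcs as _write_fcs_file
from .ingest import assign_cell_ids

__all__ = [
    "PopulationSpec",
    "SynthDesign",
    "default_design",
    "generate_dataset",
    "write_fcs",
    "write_run_inputs",
    "generate_imaging_table",
]

DEFAULT_CHANNELS = [
    "Nd143Di", "Nd145Di", "Nd146Di", "Sm147Di", "Nd148Di",
    "Sm149Di", "Nd150Di", "Eu151Di", "Sm152Di", "Eu153Di",
]
DEFAULT_MARKERS = ["CD3", "CD4", "CD8", "CD19", "CD14", "CD56", "HLA-DR", "CD45RA", "CD16", "CD11c"]

_HI, _LO = 3.5, 0.5


def _signature(high: list[int], n_markers: int) -> np.ndarray:
    sig = np.full(n_markers, _LO)
    sig[high] = _HI
    return sig


@dataclass
class PopulationSpec:
    name: str
    signature: np.ndarray  # per-marker mean, arcsinh scale
    spread: np.ndarray  # per-marker sd, > 0
    proportion: float
    stroma_affinity: float = 0.5  # used only by the imaging generator

    def __post_init__(self) -> None:
        self.signature = np.asarray(self.signature, dtype=np.float64)
        self.spread = np.broadcast_to(
            np.asarray(self.spread, dtype=np.float64), self.signature.shape
        ).copy()
        if (self.spread <= 0).any():
            raise ValueError(f"population {self.name}: spreads must be > 0")


@dataclass
class SynthDesign:
    populations: list[PopulationSpec]
    n_files: int = 6
    events_per_file: int = 1000
    channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    marker_names: list[str] = field(default_factory=lambda: list(DEFAULT_MARKERS))
    n_batches: int = 2
    batch_shift: float = 0.15  # additive arcsinh-scale offset per batch step
    control_files: list[int] = field(default_factory=list)  # default: first file of each batch
    cofactor: float = 5.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_files < 1 or self.events_per_file < 1:
            raise ValueError("n_files and events_per_file must be >= 1")
        total = sum(p.proportion for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population proportions must sum to 1, got {total}")
        if not self.control_files:
            per_batch = -(-self.n_files // self.n_batches)
            self.control_files = [b * per_batch for b in range(self.n_batches) if b * per_batch < self.n_files]

    @property
    def file_names(self) -> list[str]:
        return [f"sample_{i + 1:02d}.fcs" for i in range(self.n_files)]

    def batch_of(self, file_index: int) -> int:
        per_batch = -(-self.n_files // self.n_batches)
        return file_index // per_batch


def default_design(**overrides) -> SynthDesign:
    """Five well-separated immune-like populations over ten markers."""
    n = len(DEFAULT_MARKERS)
    pops = [
        PopulationSpec("CD4_T", _signature([0, 1, 7], n), 0.3, 0.30, stroma_affinity=0.5),
        PopulationSpec("CD8_T", _signature([0, 2, 7], n), 0.3, 0.25, stroma_affinity=0.5),
        PopulationSpec("B", _signature([3, 6], n), 0.3, 0.15, stroma_affinity=0.5),
        PopulationSpec("Mono", _signature([4, 6, 9], n), 0.3, 0.20, stroma_affinity=0.5),
        PopulationSpec("NK", _signature([5, 8], n), 0.3, 0.10, stroma_affinity=0.5),
    ]
    return SynthDesign(populations=pops, **overrides)


def _marker_metadata(design: SynthDesign) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "channel_name": design.channels,
            "marker_name": design.marker_names,
            "used_for_UMAP": True,
            "used_for_clustering": True,
            "used_for_scaffold": True,
        }
    )


def _file_metadata(design: SynthDesign) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "file_name": design.file_names,
            "donor_id": [f"donor_{design.batch_of(i) + 1}_{i + 1}" for i in range(design.n_files)],
            "pool_id": [f"batch_{design.batch_of(i) + 1}" for i in range(design.n_files)],
            "control_sample": [i in design.control_files for i in range(design.n_files)],
        }
    )


def generate_dataset(design: SynthDesign) -> tuple[CellTable, pd.DataFrame, pd.DataFrame]:
    """Draw the full dataset; returns (table, file_metadata, marker_metadata).

    The table carries raw counts, the forward-transformed matrix, and a
    ``population`` ground-truth column. Bitwise-identical for a fixed seed.
    """
    rng = np.random.default_rng(design.seed)
    props = np.array([p.proportion for p in design.populations])
    sigs = np.vstack([p.signature for p in design.populations])
    spreads = np.vstack([p.spread for p in design.populations])

    blocks, metas = [], []
    for i, fname in enumerate(design.file_names):
        n = design.events_per_file
        pop_idx = rng.choice(len(props), size=n, p=props)
        shift = design.batch_shift * design.batch_of(i)
        trans = rng.normal(sigs[pop_idx] + shift, spreads[pop_idx])
        raw = np.maximum(design.cofactor * np.sinh(trans), 0.0)
        blocks.append(raw)
        metas.append(
            pd.DataFrame(
                {
                    "file_name": fname,
                    "donor_id": f"donor_{design.batch_of(i) + 1}_{i + 1}",
                    "pool_id": f"batch_{design.batch_of(i) + 1}",
                    "control_sample": i in design.control_files,
                    "population": [design.populations[j].name for j in pop_idx],
                }
            )
        )
    raw_all = np.vstack(blocks)
    table = CellTable(
        channels=list(design.channels),
        cell_meta=pd.concat(metas, ignore_index=True),
        raw_expr=raw_all,
        trans_expr=np.arcsinh(raw_all / design.cofactor),
        cofactor=design.cofactor,
    )
    return assign_cell_ids(table), _file_metadata(design), _marker_metadata(design)


def write_fcs(table: CellTable, out_dir: str | Path) -> list[Path]:
    """One FCS 3.1 file (float32) per source file; readable by the intake."""
    if table.raw_expr is None:
        raise ValueError("table has no raw expression matrix to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for fname, group in table.cell_meta.groupby("file_name", sort=False):
        rows = group.index.to_numpy()
        df = pd.DataFrame(table.raw_expr[rows], columns=table.channels)
        path = out_dir / str(fname)
        _write_fcs_file(path, df)
        written.append(path)
    return written


def write_run_inputs(
    design: SynthDesign,
    directory: str | Path,
    with_landmarks: bool = True,
    landmark_events: int = 300,
    config_overrides: dict | None = None,
) -> dict[str, Path]:
    """Emit the complete on-disk input set for a pipeline run.

    Writes the FCS directory, file_metadata.csv, marker_metadata.csv,
    config.yml, the ground-truth label table, and (optionally) a landmark
    directory holding one gated FCS file per planted population drawn from
    that population's signature. Returns the path map.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table, files, markers = generate_dataset(design)

    fcs_dir = directory / "fcs"
    write_fcs(table, fcs_dir)
    files.to_csv(directory / "file_metadata.csv", index=False)
    markers.to_csv(directory / "marker_metadata.csv", index=False)
    table.cell_meta[["cell_id", "population"]].rename(columns={"population": "label"}).to_csv(
        directory / "truth_labels.csv", index=False
    )

    paths = {
        "dir": directory,
        "fcs_dir": fcs_dir,
        "file_metadata": directory / "file_metadata.csv",
        "marker_metadata": directory / "marker_metadata.csv",
        "truth_labels": directory / "truth_labels.csv",
        "config": directory / "config.yml",
    }

    if with_landmarks:
        lm_dir = directory / "landmarks"
        lm_dir.mkdir(exist_ok=True)
        rng = np.random.default_rng(design.seed + 1)
        for pop in design.populations:
            trans = rng.normal(pop.signature, pop.spread, size=(landmark_events, len(design.channels)))
            raw = np.maximum(design.cofactor * np.sinh(trans), 0.0)
            _write_fcs_file(lm_dir / f"{pop.name}.fcs", pd.DataFrame(raw, columns=design.channels))
        paths["landmark_dir"] = lm_dir

    config = {
        "fcs_dir": str(fcs_dir),
        "output_dir": str(directory / "out"),
        "file_metadata_path": str(paths["file_metadata"]),
        "marker_metadata_path": str(paths["marker_metadata"]),
        "truth_labels_path": str(paths["truth_labels"]),
        "arcsinh_cofactor": design.cofactor,
        "backend": "som",
        "som_params": {"xdim": 6, "ydim": 6, "seed": design.seed},
        "umap_params": {"seed": design.seed},
    }
    if with_landmarks:
        config["landmark_dir"] = str(paths["landmark_dir"])
    if config_overrides:
        config.update(config_overrides)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh)
    return paths


def generate_imaging_table(
    design: SynthDesign,
    n_cells: int = 5000,
    width: float = 1000.0,
    height: float = 1000.0,
) -> tuple[CellTable, pd.DataFrame]:
    """Imaging-style input: arcsinh expression plus centroids and regions.

    Cells are placed uniformly in a ``width x height`` rectangle whose left
    half is stroma and right half tumor; each population lands in the stroma
    half with probability ``stroma_affinity`` (0.5 = no spatial bias), which
    plants known enrichment. Returns an already-transformed CellTable and a
    region table {cell_id, x, y, region}.
    """
    rng = np.random.default_rng(design.seed)
    props = np.array([p.proportion for p in design.populations])
    pop_idx = rng.choice(len(props), size=n_cells, p=props)
    sigs = np.vstack([p.signature for p in design.populations])
    spreads = np.vstack([p.spread for p in design.populations])
    trans = rng.normal(sigs[pop_idx], spreads[pop_idx])

    affinity = np.array([p.stroma_affinity for p in design.populations])[pop_idx]
    in_stroma = rng.random(n_cells) < affinity
    x = np.where(
        in_stroma,
        rng.uniform(0, width / 2, size=n_cells),
        rng.uniform(width / 2, width, size=n_cells),
    )
    y = rng.uniform(0, height, size=n_cells)

    meta = pd.DataFrame(
        {
            "file_name": "imaging_roi",
            "donor_id": "imaging",
            "pool_id": "imaging",
            "control_sample": False,
            "population": [design.populations[j].name for j in pop_idx],
        }
    )
    table = CellTable(
        channels=list(design.channels),
        cell_meta=meta,
        trans_expr=trans,
        cofactor=design.cofactor,
    )
    table = assign_cell_ids(table)
    regions = pd.DataFrame(
        {
            "cell_id": table.cell_meta["cell_id"],
            "x": x,
            "y": y,
            "region": np.where(in_stroma, "stroma", "tumor"),
        }
    )
    return table, regions
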