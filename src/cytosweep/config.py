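"""Run configuration and the two metadata tables steering a pipeline run.

A run is described by three files: ``file_metadata.csv`` (one row per FCS
file: ``file_name``, ``donor_id``, ``pool_id`` i.e. batch, ``control_sample``),
``marker_metadata.csv`` (one row per channel: ``channel_name``,
``marker_name`` and the three boolean usage flags ``used_for_UMAP``,
``used_for_clustering``, ``used_for_scaffold``), and ``config.yml`` with the
processing parameters. Absent config keys fall back to the documented
defaults (arcsinh cofactor 5; UMAP n_neighbors 15, min_dist 0.1, spread 0.1,
learning_rate 0.5, random init; SOM grid 6x6, metaclustering off with k=3;
CLARA k=20, euclidean, 50 subsamples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

__all__ = [
    "UmapParams",
    "SomParams",
    "ClaraParams",
    "PipelineConfig",
    "read_file_metadata",
    "read_marker_metadata",
    "read_config",
    "read_metadata",
    "marker_channels",
]

_BOOL_VOCAB = {
    "true": True, "false": False,
    "TRUE": True, "FALSE": False,
    "True": True, "False": False,
    "1": True, "0": False,
    1: True, 0: False,
    True: True, False: False,
}

FILE_COLUMNS = ["file_name", "donor_id", "pool_id", "control_sample"]
MARKER_COLUMNS = [
    "channel_name",
    "marker_name",
    "used_for_UMAP",
    "used_for_clustering",
    "used_for_scaffold",
]


class SchemaError(ValueError):
    """A required column is missing or a value fails to parse."""


class ConfigError(ValueError):
    """config.yml carries an invalid or inconsistent value."""


def _parse_bool_column(series: pd.Series, column: str) -> pd.Series:
    out = []
    for idx, value in series.items():
        if isinstance(value, str):
            value = value.strip()
        if value not in _BOOL_VOCAB:
            raise SchemaError(
                f"column {column!r}, row {idx}: {value!r} is not an accepted "
                "boolean (true/false, TRUE/FALSE, 1/0)"
            )
        out.append(_BOOL_VOCAB[value])
    return pd.Series(out, index=series.index, dtype=bool)


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{what}: ignoring unrecognised column(s) {extra}", stacklevel=3)


def read_file_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, FILE_COLUMNS, "file_metadata.csv")
    df = df[FILE_COLUMNS].copy()
    df["control_sample"] = _parse_bool_column(df["control_sample"], "control_sample")
    if df["file_name"].duplicated().any():
        dupes = df.loc[df["file_name"].duplicated(), "file_name"].tolist()
        raise SchemaError(f"file_metadata.csv: duplicated file_name entries {dupes}")
    return df


def read_marker_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, MARKER_COLUMNS, "marker_metadata.csv")
    df = df[MARKER_COLUMNS].copy()
    for col in ("used_for_UMAP", "used_for_clustering", "used_for_scaffold"):
        df[col] = _parse_bool_column(df[col], col)
    if df["channel_name"].duplicated().any():
        raise SchemaError("marker_metadata.csv: channel_name values must be unique")
    if not df["used_for_clustering"].any():
        raise SchemaError("marker_metadata.csv: at least one marker must be used_for_clustering")
    return df


def marker_channels(markers: pd.DataFrame, usage: str | None = None) -> list[str]:
    """Channel names, optionally restricted to one usage flag.

    ``usage`` is one of ``"umap"``, ``"clustering"``, ``"scaffold"`` or None
    for all channels.
    """
    if usage is None:
        return list(markers["channel_name"])
    flag = {
        "umap": "used_for_UMAP",
        "clustering": "used_for_clustering",
        "scaffold": "used_for_scaffold",
    }[usage]
    return list(markers.loc[markers[flag], "channel_name"])


@dataclass
class UmapParams:
    n_neighbors: int = 15
    min_dist: float = 0.1
    spread: float = 0.1
    learning_rate: float = 0.5
    init: str = "random"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.min_dist > self.spread:
            warnings.warn(
                f"umap: spread ({self.spread}) raised to min_dist "
                f"({self.min_dist}); min_dist must not exceed spread"
            )
            self.spread = self.min_dist


@dataclass
class SomParams:
    xdim: int = 6
    ydim: int = 6
    meta_clustering: bool = False
    k: int = 3  # metacluster count when meta_clustering is on
    seed: int = 42
    rlen: int = 10
    alpha_start: float = 0.05
    alpha_end: float = 0.01

    def __post_init__(self) -> None:
        if self.xdim < 1 or self.ydim < 1:
            raise ConfigError(f"SOM grid must be at least 1x1, got {self.xdim}x{self.ydim}")


@dataclass
class ClaraParams:
    k: int = 20
    metric: str = "euclidean"
    samples: int = 50
    seed: int = 42

    def __post_init__(self) -> None:
        if self.metric not in ("euclidean", "manhattan"):
            raise ConfigError(f"unsupported CLARA metric {self.metric!r}")


@dataclass
class PipelineConfig:
    fcs_dir: Path = Path(".")
    output_dir: Path = Path("cytosweep_out")
    file_metadata_path: Path = Path("file_metadata.csv")
    marker_metadata_path: Path = Path("marker_metadata.csv")
    arcsinh_cofactor: float = 5.0
    umap_params: UmapParams = field(default_factory=UmapParams)
    backend: str = "som"
    som_params: SomParams = field(default_factory=SomParams)
    clara_params: ClaraParams = field(default_factory=ClaraParams)
    grid_sizes_path: Path | None = None
    landmark_dir: Path | None = None
    truth_labels_path: Path | None = None
    subsample_per_file: int | None = None
    remove_controls: bool = False
    already_transformed: bool = False
    matrix_path: Path | None = None
    cell_meta_path: Path | None = None

    def __post_init__(self) -> None:
        if self.arcsinh_cofactor <= 0:
            raise ConfigError(f"arcsinh_cofactor must be > 0, got {self.arcsinh_cofactor}")
        if self.backend not in ("som", "clara"):
            raise ConfigError(f"unknown clustering backend {self.backend!r}")
        if self.subsample_per_file is not None and self.subsample_per_file < 1:
            raise ConfigError("subsample_per_file must be >= 1 when set")
        for attr in (
            "fcs_dir", "output_dir", "file_metadata_path", "marker_metadata_path",
            "grid_sizes_path", "landmark_dir", "truth_labels_path",
            "matrix_path", "cell_meta_path",
        ):
            value = getattr(self, attr)
            if value is not None:
                setattr(self, attr, Path(value))

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


def read_config(path: str | Path) -> PipelineConfig:
    """Parse config.yml, filling documented defaults for absent keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known_nested = {"umap_params": UmapParams, "som_params": SomParams, "clara_params": ClaraParams}
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in known_nested:
            if not isinstance(value, dict):
                raise ConfigError(f"{path}: {key} must be a mapping")
            kwargs[key] = known_nested[key](**value)
        elif key in PipelineConfig.__dataclass_fields__:
            kwargs[key] = value
        else:
            warnings.warn(f"{path}: ignoring unknown config key {key!r}")
    return PipelineConfig(**kwargs)


def read_metadata(
    file_md_path: str | Path,
    marker_md_path: str | Path,
    config_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, PipelineConfig]:
    """Read the three run-definition files together, with referential checks."""
    files = read_file_metadata(file_md_path)
    markers = read_marker_metadata(marker_md_path)
    cfg = read_config(config_path)
    return files, markers, cfg
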