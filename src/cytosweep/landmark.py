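"""Anchoring clusters to expert-gated landmark populations.

Each landmark is a gated FCS file of a known population; its profile is the
median arcsinh-transformed expression over the markers flagged
``used_for_scaffold``. Every non-empty cluster is assigned to the landmark
whose profile has the highest cosine similarity with the cluster's median
profile — a scale-invariant match, so overall staining intensity differences
between the landmark files and the run do not drive the assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import marker_channels
from .fcsio import read_fcs
from .transform import arcsinh_transform

__all__ = ["LandmarkSet", "load_landmarks", "cosine_similarity", "assign_landmarks"]


@dataclass
class LandmarkSet:
    names: list[str]
    profiles: pd.DataFrame  # landmark x scaffold-marker medians


def load_landmarks(
    directory: str | Path, markers: pd.DataFrame, cofactor: float
) -> LandmarkSet:
    """One profile per gated FCS file; the name is the filename stem."""
    directory = Path(directory)
    channels = marker_channels(markers, "scaffold")
    if not channels:
        raise ValueError("no markers are flagged used_for_scaffold")
    paths = sorted(directory.glob("*.fcs"))
    if not paths:
        raise ValueError(f"no FCS files found in landmark directory {directory}")
    names: list[str] = []
    rows = []
    for path in paths:
        if path.stem in names:
            raise ValueError(f"duplicate landmark name {path.stem!r}")
        data, _ = read_fcs(path)
        missing = [c for c in channels if c not in data.columns]
        if missing:
            raise ValueError(f"landmark {path.name} lacks channel(s) {missing}")
        trans = arcsinh_transform(data[channels].to_numpy(), cofactor)
        names.append(path.stem)
        rows.append(np.median(trans, axis=0))
    profiles = pd.DataFrame(rows, index=names, columns=channels)
    return LandmarkSet(names=names, profiles=profiles)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """a.b / (|a||b|); undefined (raises) when either vector has zero norm."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"vector shapes differ: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero-norm vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def assign_landmarks(
    median_expr: pd.DataFrame,
    landmarks: LandmarkSet,
    markers: pd.DataFrame,
) -> pd.DataFrame:
    """Closest landmark per cluster by cosine similarity on scaffold markers.

    Returns a table {cluster, landmark, cosine}. Ties go to the
    lexicographically first landmark name (logged); clusters whose profile
    has zero norm (or no events, i.e. NaN medians) come back "unassigned".
    """
    channels = marker_channels(markers, "scaffold")
    missing = [c for c in channels if c not in median_expr.columns]
    if missing:
        raise ValueError(f"median expression lacks scaffold marker(s) {missing}")
    profiles = landmarks.profiles[channels]
    order = np.argsort(landmarks.names)  # lexicographic tie-break
    rows = []
    for cluster, profile in median_expr[channels].iterrows():
        vec = profile.to_numpy(dtype=np.float64)
        if np.isnan(vec).any() or np.linalg.norm(vec) == 0:
            warnings.warn(f"{cluster}: empty or zero-norm profile, left unassigned")
            rows.append({"cluster": cluster, "landmark": "unassigned", "cosine": np.nan})
            continue
        sims = {
            landmarks.names[i]: cosine_similarity(vec, profiles.iloc[i].to_numpy())
            for i in order
        }
        best = max(sorted(sims), key=lambda name: sims[name])
        rows.append({"cluster": cluster, "landmark": best, "cosine": sims[best]})
    return pd.DataFrame(rows)
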