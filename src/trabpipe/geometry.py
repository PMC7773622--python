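"""Proximal femur geometry (PFG) from labeled 3D landmarks.

Three variables characterize hip shape: the neck shaft angle (NSA), the angle
between the femoral neck medial axis and the femoral shaft medial axis, and
two femoral neck axis lengths measured from the neck-axis start point below
the greater trochanter — FNALa to the anterior point of the femoral head and
FNALb to the femoral head center.  Landmarks arrive as a CSV with one labeled
point per row (extracting them from surfaces or images is out of scope here).

Both lengths are plain Euclidean distances, so they are invariant under rigid
motion of all landmarks; NSA is additionally invariant under uniform scaling.
Callers pass the shaft direction pointing distal-to-proximal so the anatomical
(obtuse-side) angle is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FemurLandmarks",
    "PFG",
    "neck_shaft_angle",
    "fnal",
    "compute_pfg",
    "PFG_FEATURE_NAMES",
    "LANDMARK_LABELS",
]

PFG_FEATURE_NAMES = ["nsa", "fnala", "fnalb"]
LANDMARK_LABELS = ["neck_start", "head_anterior", "head_center", "shaft_p1", "shaft_p2"]


@dataclass
class FemurLandmarks:
    """Labeled 3D points (mm): neck-axis start, head anterior point, head
    center, and two femoral shaft axis points ordered distal to proximal."""

    neck_start: np.ndarray
    head_anterior: np.ndarray
    head_center: np.ndarray
    shaft_p1: np.ndarray
    shaft_p2: np.ndarray

    def __post_init__(self) -> None:
        for name in LANDMARK_LABELS:
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"landmark {name!r} must be a finite 3D point")
            setattr(self, name, v)

    @property
    def neck_direction(self) -> np.ndarray:
        return self.head_center - self.neck_start

    @property
    def shaft_direction(self) -> np.ndarray:
        # distal-to-proximal
        return self.shaft_p2 - self.shaft_p1

    @classmethod
    def from_csv(cls, path: str | Path) -> "FemurLandmarks":
        df = pd.read_csv(path)
        required = {"label", "x_mm", "y_mm", "z_mm"}
        if not required.issubset(df.columns):
            raise ValueError(f"landmark CSV needs columns {sorted(required)}")
        points = {}
        for label in LANDMARK_LABELS:
            row = df[df["label"] == label]
            if len(row) != 1:
                raise ValueError(f"landmark CSV must contain exactly one {label!r} row")
            points[label] = row[["x_mm", "y_mm", "z_mm"]].to_numpy()[0]
        return cls(**points)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"label": label, **dict(zip(["x_mm", "y_mm", "z_mm"], getattr(self, label)))}
            for label in LANDMARK_LABELS
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class PFG:
    nsa: float    # degrees
    fnala: float  # mm
    fnalb: float  # mm

    def as_series(self) -> pd.Series:
        return pd.Series([self.nsa, self.fnala, self.fnalb], index=PFG_FEATURE_NAMES)


def neck_shaft_angle(neck_direction: np.ndarray, shaft_direction: np.ndarray) -> float:
    """Angle in degrees, in (0, 180], between the neck and shaft axes."""
    u = np.asarray(neck_direction, dtype=float)
    v = np.asarray(shaft_direction, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("axis direction vectors must be nonzero")
    cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def fnal(landmarks: FemurLandmarks) -> tuple[float, float]:
    """(FNALa, FNALb): distances from the neck-axis start to the head anterior
    point and head center respectively."""
    a = float(np.linalg.norm(landmarks.head_anterior - landmarks.neck_start))
    b = float(np.linalg.norm(landmarks.head_center - landmarks.neck_start))
    if a == 0 or b == 0:
        warnings.warn("coincident landmarks give a zero neck axis length", stacklevel=2)
    return a, b


def compute_pfg(landmarks: FemurLandmarks) -> PFG:
    """NSA, FNALa and FNALb from one femur's landmark set."""
    nsa = neck_shaft_angle(landmarks.neck_direction, landmarks.shaft_direction)
    a, b = fnal(landmarks)
    return PFG(nsa, a, b)
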