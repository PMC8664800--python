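"""Facial-geometry feature space: 30 measures from 68-point landmarks.

Input is the iBUG 300-W landmark convention (jaw 0-16, brows 17-26, nose
27-35, eyes 36-47, mouth 48-67) in image pixels, plus an optional
precomputed median skin luminance (a segmentation-mask statistic consumed
as a scalar; no image parsing happens here). Faces are canonicalized —
rotated so the pupil line is horizontal, without reflection — before
measuring, making every feature invariant to in-plane rotation and
translation. Distances are in pixels; ratio features are additionally
scale-invariant.

The feature definitions live in :data:`FEATURE_REGISTRY`, one documented
formula per feature, so individual definitions can be revised without
touching the pipeline. Named measures follow conventions of the
social-perception literature (e.g., fWHR = bizygomatic width / midface
length); where the literature names a measure without fixing a formula,
the registry entry documents the definition adopted here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from facejudge.tables import FeatureTable

__all__ = [
    "LandmarkSet",
    "GeometryFeatureVector",
    "FEATURE_NAMES",
    "FEATURE_REGISTRY",
    "compute_geometry_features",
    "batch_geometry_table",
]

GEOMETRY_SPACE_NAME = "facial-geometry"

# eye landmark blocks (image-right eye = subject's right on a frontal photo)
_RIGHT_EYE = slice(36, 42)
_LEFT_EYE = slice(42, 48)


@dataclass
class LandmarkSet:
    """68 ordered (x, y) landmarks for one face, plus optional skin luminance."""

    face_id: str
    points: np.ndarray
    skin_luminance: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (68, 2):
            raise ValueError(
                f"face {self.face_id!r}: expected 68 (x, y) points, got shape {self.points.shape}"
            )
        if not np.isfinite(self.points).all():
            raise ValueError(f"face {self.face_id!r}: non-finite landmark coordinates")
        pr = self.points[_RIGHT_EYE].mean(axis=0)
        pl = self.points[_LEFT_EYE].mean(axis=0)
        if np.hypot(*(pl - pr)) <= 0:
            raise ValueError(f"face {self.face_id!r}: interocular distance is zero")
        if self.skin_luminance is not None and not 0 <= self.skin_luminance <= 255:
            raise ValueError(f"face {self.face_id!r}: skin_luminance outside [0, 255]")

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(d["face_id"], np.asarray(d["points"]), d.get("skin_luminance"))


@dataclass
class GeometryFeatureVector:
    face_id: str
    values: dict[str, float]


def _canonicalize(points: np.ndarray) -> np.ndarray:
    """Rotate so the pupil line is horizontal (left pupil at larger x)."""
    pr = points[_RIGHT_EYE].mean(axis=0)
    pl = points[_LEFT_EYE].mean(axis=0)
    dx, dy = pl - pr
    angle = np.arctan2(dy, dx)
    c, s = np.cos(-angle), np.sin(-angle)
    R = np.array([[c, -s], [s, c]])
    center = points.mean(axis=0)
    return (points - center) @ R.T + center


def _dist(p: np.ndarray, i: int, j: int) -> float:
    return float(np.hypot(*(p[i] - p[j])))


def _pd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.hypot(*(a - b)))


class _Face:
    """Primitive measurements on a canonicalized landmark set."""

    def __init__(self, lm: LandmarkSet):
        p = _canonicalize(lm.points)
        self.p = p
        self.luminance = lm.skin_luminance
        self.pupil_right = p[_RIGHT_EYE].mean(axis=0)
        self.pupil_left = p[_LEFT_EYE].mean(axis=0)
        self.pupil_mid = 0.5 * (self.pupil_left + self.pupil_right)
        self.glabella = 0.5 * (p[21] + p[22])

    def require_nonzero(self, value: float, measure: str) -> float:
        if value <= 0:
            raise ValueError(f"degenerate geometry: {measure} is zero")
        return value


# name -> (formula documentation, function of _Face)
FEATURE_REGISTRY: dict[str, tuple[str, callable]] = {
    "skin_luminance": (
        "median luminance of the skin region (precomputed scalar, 0-255)",
        lambda f: f.luminance,
    ),
    "nose_width": ("distance between nostril corners (31, 35)", lambda f: _dist(f.p, 31, 35)),
    "nose_length": ("nasion (27) to nose tip base (33)", lambda f: _dist(f.p, 27, 33)),
    "lip_thickness": (
        "upper lip (51-62) plus lower lip (66-57) vertical thickness",
        lambda f: _dist(f.p, 51, 62) + _dist(f.p, 66, 57),
    ),
    "face_length": (
        "glabella (midpoint of inner brows 21, 22) to chin point (8)",
        lambda f: f.require_nonzero(_pd(f.glabella, f.p[8]), "face length"),
    ),
    "eye_height_left": (
        "mean vertical aperture of the left eye ((43-47) and (44-46))",
        lambda f: 0.5 * (_dist(f.p, 43, 47) + _dist(f.p, 44, 46)),
    ),
    "eye_height_right": (
        "mean vertical aperture of the right eye ((37-41) and (38-40))",
        lambda f: 0.5 * (_dist(f.p, 37, 41) + _dist(f.p, 38, 40)),
    ),
    "eye_width_left": ("left eye corner distance (42, 45)", lambda f: _dist(f.p, 42, 45)),
    "eye_width_right": ("right eye corner distance (36, 39)", lambda f: _dist(f.p, 36, 39)),
    "face_width_cheek": (
        "bizygomatic width: jaw points (1, 15) at cheekbone level",
        lambda f: f.require_nonzero(_dist(f.p, 1, 15), "face width at cheek"),
    ),
    "face_width_mouth": (
        "jaw width at mouth level: jaw points (4, 12)",
        lambda f: f.require_nonzero(_dist(f.p, 4, 12), "face width at mouth"),
    ),
    "pupil_distance": (
        "distance between pupil proxies (centroids of eye landmarks)",
        lambda f: f.require_nonzero(_pd(f.pupil_left, f.pupil_right), "pupil distance"),
    ),
    "pupil_lip_left": (
        "left pupil proxy to upper-lip top center (51)",
        lambda f: _pd(f.pupil_left, f.p[51]),
    ),
    "pupil_lip_right": (
        "right pupil proxy to upper-lip top center (51)",
        lambda f: _pd(f.pupil_right, f.p[51]),
    ),
    "pupil_lip_asymmetry": (
        "absolute left/right difference of the pupil-to-upper-lip distances",
        lambda f: abs(_pd(f.pupil_left, f.p[51]) - _pd(f.pupil_right, f.p[51])),
    ),
    "chin_length": ("lower-lip bottom (57) to chin point (8)", lambda f: _dist(f.p, 57, 8)),
    "cheek_to_chin_left": ("left cheek (15) to chin (8)", lambda f: _dist(f.p, 15, 8)),
    "cheek_to_chin_right": ("right cheek (1) to chin (8)", lambda f: _dist(f.p, 1, 8)),
    "face_shape": (
        "elongation: face length / face width at cheek",
        lambda f: _pd(f.glabella, f.p[8]) / f.require_nonzero(_dist(f.p, 1, 15), "face width at cheek"),
    ),
    "heartshapeness": (
        "cheek width / jaw width at mouth level (taper toward the chin)",
        lambda f: _dist(f.p, 1, 15) / f.require_nonzero(_dist(f.p, 4, 12), "face width at mouth"),
    ),
    "nose_shape": (
        "nose width / nose length",
        lambda f: _dist(f.p, 31, 35) / f.require_nonzero(_dist(f.p, 27, 33), "nose length"),
    ),
    "lip_fullness": (
        "lip thickness / face length",
        lambda f: (_dist(f.p, 51, 62) + _dist(f.p, 66, 57))
        / f.require_nonzero(_pd(f.glabella, f.p[8]), "face length"),
    ),
    "eye_shape": (
        "mean eye height / mean eye width",
        lambda f: (0.5 * (_dist(f.p, 43, 47) + _dist(f.p, 44, 46)) + 0.5 * (_dist(f.p, 37, 41) + _dist(f.p, 38, 40)))
        / f.require_nonzero(_dist(f.p, 42, 45) + _dist(f.p, 36, 39), "eye width"),
    ),
    "eye_size": (
        "mean of left/right eye height x width areas (pixels^2)",
        lambda f: 0.5
        * (
            0.5 * (_dist(f.p, 43, 47) + _dist(f.p, 44, 46)) * _dist(f.p, 42, 45)
            + 0.5 * (_dist(f.p, 37, 41) + _dist(f.p, 38, 40)) * _dist(f.p, 36, 39)
        ),
    ),
    "midface_length": (
        "pupil-line midpoint to upper-lip top center (51)",
        lambda f: f.require_nonzero(_pd(f.pupil_mid, f.p[51]), "midface length"),
    ),
    "chin_size": (
        "chin length / face length",
        lambda f: _dist(f.p, 57, 8) / f.require_nonzero(_pd(f.glabella, f.p[8]), "face length"),
    ),
    "cheekbone_height": (
        "vertical drop from the pupil line to the cheek-width line, / face length",
        lambda f: (0.5 * (f.p[1, 1] + f.p[15, 1]) - f.pupil_mid[1])
        / f.require_nonzero(_pd(f.glabella, f.p[8]), "face length"),
    ),
    "cheekbone_prominence": (
        "cheek width / mid-jaw width (jaw points 3, 13)",
        lambda f: _dist(f.p, 1, 15) / f.require_nonzero(_dist(f.p, 3, 13), "mid-jaw width"),
    ),
    "face_roundness": (
        "face width at cheek / face length",
        lambda f: _dist(f.p, 1, 15) / f.require_nonzero(_pd(f.glabella, f.p[8]), "face length"),
    ),
    "fwhr": (
        "facial width-to-height ratio: cheek width / midface length",
        lambda f: _dist(f.p, 1, 15) / f.require_nonzero(_pd(f.pupil_mid, f.p[51]), "midface length"),
    ),
}

FEATURE_NAMES: list[str] = list(FEATURE_REGISTRY)
assert len(FEATURE_NAMES) == 30


def compute_geometry_features(
    landmarks: LandmarkSet, include_luminance: bool = True
) -> GeometryFeatureVector:
    """All 30 geometry features for one face; pure function of its input.

    Raises if the luminance feature is requested but absent, or if a
    degenerate measurement (zero face width/length etc.) is encountered —
    the error names the offending measure.
    """
    if include_luminance and landmarks.skin_luminance is None:
        raise ValueError(
            f"face {landmarks.face_id!r}: skin_luminance missing but the "
            "luminance feature was requested"
        )
    face = _Face(landmarks)
    values: dict[str, float] = {}
    for name, (_, fn) in FEATURE_REGISTRY.items():
        if name == "skin_luminance" and not include_luminance:
            continue
        values[name] = float(fn(face))
    return GeometryFeatureVector(landmarks.face_id, values)


def batch_geometry_table(
    landmark_sets: list[LandmarkSet], include_luminance: bool = True
) -> FeatureTable:
    """Geometry features for many faces as one feature table."""
    if not landmark_sets:
        raise ValueError("landmark_sets must be non-empty")
    ids = [lm.face_id for lm in landmark_sets]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate face_id(s): {dupes}")
    rows = [compute_geometry_features(lm, include_luminance).values for lm in landmark_sets]
    df = pd.DataFrame(rows, index=ids)
    return FeatureTable(GEOMETRY_SPACE_NAME, df)
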