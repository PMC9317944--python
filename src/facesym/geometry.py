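"""Landmark containers, 68->51 renumbering, tilt correction and rotation augmentation.

Coordinates follow the image convention: x grows rightward, y grows downward,
units are pixels.  The 51-point numbering places the outer eye corners at
indices 10 (image-left) and 19 (image-right); those two points anchor the
in-plane tilt correction.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "DegenerateGeometryError",
    "Point2D",
    "LandmarkSet68",
    "LandmarkSet51",
    "SimilarityTransform",
    "AcquisitionScale",
    "load_mapping",
    "default_mapping",
    "renumber_landmarks",
    "estimate_tilt_transform",
    "apply_transform",
    "tilt_correct",
    "rotate_augment",
    "MIRROR_INDEX_MAP",
    "OUTER_LEFT_EYE",
    "OUTER_RIGHT_EYE",
]


class GeometryError(ValueError):
    """Invalid landmark geometry or configuration."""


class DegenerateGeometryError(GeometryError):
    """Geometry that makes an operation undefined (coincident points, ...)."""


#: 51-point indices of the outer eye corners (image-left / image-right).
OUTER_LEFT_EYE = 10
OUTER_RIGHT_EYE = 19

#: 51-point indices of the mouth corners on the outer lip contour.
LEFT_MOUTH_CORNER = 28
RIGHT_MOUTH_CORNER = 34


class Point2D(NamedTuple):
    x: float
    y: float


def _as_points(points, n: int, what: str) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.shape != (n, 2):
        raise GeometryError(f"{what} requires shape ({n}, 2), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise GeometryError(f"{what} contains non-finite coordinates")
    return arr


@dataclass(frozen=True)
class LandmarkSet68:
    """Raw 68-point facial landmark set in the standard full-face layout."""

    points: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "points", _as_points(self.points, 68, "LandmarkSet68"))

    def __len__(self) -> int:
        return 68


@dataclass(frozen=True)
class LandmarkSet51:
    """The 51 renumbered key points P0..P50 used for feature computation."""

    points: np.ndarray
    source_id: str = ""
    tilt_corrected: bool = False

    def __post_init__(self):
        object.__setattr__(self, "points", _as_points(self.points, 51, "LandmarkSet51"))

    def __len__(self) -> int:
        return 51

    def point(self, i: int) -> Point2D:
        return Point2D(*self.points[i])

    @property
    def eye_corners(self) -> tuple[Point2D, Point2D]:
        return self.point(OUTER_LEFT_EYE), self.point(OUTER_RIGHT_EYE)

    @property
    def eye_midpoint(self) -> Point2D:
        l, r = self.eye_corners
        return Point2D((l.x + r.x) / 2.0, (l.y + r.y) / 2.0)


@dataclass(frozen=True)
class AcquisitionScale:
    """Resize parameters for the optional image-acquisition path.

    sf = W / nW with a fixed detection width nW (default 200 px) and the
    derived height nH = H / sf.  Applies only to images, never to stored
    landmark coordinates.
    """

    sf: float
    nW: int = 200
    nH: float = 0.0

    def __post_init__(self):
        if self.sf <= 0:
            raise GeometryError("scale factor sf must be positive")

    @classmethod
    def for_image(cls, width: int, height: int, nW: int = 200) -> "AcquisitionScale":
        sf = width / nW
        return cls(sf=sf, nW=nW, nH=height / sf)


# --------------------------------------------------------------------------
# 68 -> 51 renumbering
# --------------------------------------------------------------------------

def load_mapping(path) -> np.ndarray:
    """Load a 68->51 renumbering table from a CSV with columns col68,colP.

    Returns an array ``m`` of length 51 where ``m[p]`` is the 68-layout index
    feeding point ``Pp``.  The table must be a bijection from 51 distinct
    68-layout indices onto 0..50.
    """
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append((int(rec["col68"]), int(rec["colP"])))
    return _validate_mapping(rows)


def _validate_mapping(rows: Sequence[tuple[int, int]]) -> np.ndarray:
    if len(rows) != 51:
        raise GeometryError(f"mapping must have 51 rows, got {len(rows)}")
    m = np.full(51, -1, dtype=int)
    seen68 = set()
    for c68, cp in rows:
        if not (0 <= c68 < 68):
            raise GeometryError(f"mapping references 68-layout index {c68} out of range")
        if not (0 <= cp < 51):
            raise GeometryError(f"mapping references P index {cp} out of range")
        if c68 in seen68:
            raise GeometryError(f"mapping is not injective: 68-layout index {c68} reused")
        if m[cp] != -1:
            raise GeometryError(f"mapping assigns P{cp} twice")
        seen68.add(c68)
        m[cp] = c68
    return m


_DEFAULT_MAPPING: np.ndarray | None = None


def default_mapping() -> np.ndarray:
    """The packaged renumbering: contour points dropped, organs re-indexed."""
    global _DEFAULT_MAPPING
    if _DEFAULT_MAPPING is None:
        ref = resources.files("facesym.data") / "mapping_68_to_51.csv"
        with resources.as_file(ref) as p:
            _DEFAULT_MAPPING = load_mapping(p)
    return _DEFAULT_MAPPING


def renumber_landmarks(full: LandmarkSet68, mapping: np.ndarray | None = None) -> LandmarkSet51:
    """Select and reorder the 51 points of interest from a 68-point set.

    Coordinates are carried over unchanged; only indices are remapped.
    """
    if not isinstance(full, LandmarkSet68):
        full = LandmarkSet68(np.asarray(full, dtype=float))
    if mapping is None:
        mapping = default_mapping()
    else:
        mapping = _validate_mapping([(int(c68), p) for p, c68 in enumerate(np.asarray(mapping))])
    return LandmarkSet51(full.points[mapping], source_id=full.source_id)


#: Mirror homologue of each P index under reflection about the facial midline.
MIRROR_INDEX_MAP = np.array(
    [9, 8, 7, 6, 5, 4, 3, 2, 1, 0,           # eyebrows
     19, 18, 17, 16, 21, 20,                 # left eye -> right eye
     13, 12, 11, 10, 15, 14,                 # right eye -> left eye
     22,                                     # nose bridge top (midline)
     27, 26, 25, 24, 23,                     # nose bottom row
     34, 33, 32, 31, 30, 29, 28,             # outer lip, upper arc
     39, 38, 37, 36, 35,                     # outer lip, lower arc
     44, 43, 42, 41, 40, 47, 46, 45,         # inner lip
     48, 49, 50],                            # nose bridge (midline)
    dtype=int,
)


# --------------------------------------------------------------------------
# Similarity transform
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityTransform:
    """A 2x3 affine matrix restricted to rotation + uniform scale + translation.

    The upper-left 2x2 block has the form [[a, -b], [b, a]] with positive
    determinant a^2 + b^2.
    """

    m: np.ndarray

    _FORM_TOL = 1e-9

    def __post_init__(self):
        m = np.asarray(self.m, dtype=float)
        if m.shape != (2, 3):
            raise GeometryError(f"transform matrix must be 2x3, got {m.shape}")
        a, nb = m[0, 0], m[0, 1]
        b, a2 = m[1, 0], m[1, 1]
        if abs(a - a2) > self._FORM_TOL or abs(nb + b) > self._FORM_TOL:
            raise GeometryError("2x2 block is not of rotation+uniform-scale form")
        if a * a2 - nb * b <= 0:
            raise GeometryError("transform must have positive determinant")
        object.__setattr__(self, "m", m)

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_params(cls, a: float, b: float, tx: float, ty: float) -> "SimilarityTransform":
        return cls(np.array([[a, -b, tx], [b, a, ty]]))

    @classmethod
    def rotation(cls, angle_rad: float, center=(0.0, 0.0), scale: float = 1.0) -> "SimilarityTransform":
        """Rotation by ``angle_rad`` about ``center`` with optional uniform scale."""
        a = scale * math.cos(angle_rad)
        b = scale * math.sin(angle_rad)
        cx, cy = center
        tx = cx - a * cx + b * cy
        ty = cy - b * cx - a * cy
        return cls.from_params(a, b, tx, ty)

    @classmethod
    def from_point_pairs(cls, src, dst) -> "SimilarityTransform":
        """Closed-form similarity taking two source points onto two targets.

        Two point pairs give four equations for the four unknowns
        (a, b, tx, ty); treating points as complex numbers, the linear part
        is (dst2 - dst1) / (src2 - src1).
        """
        (s1, s2), (d1, d2) = np.asarray(src, float), np.asarray(dst, float)
        zs = complex(s2[0] - s1[0], s2[1] - s1[1])
        zd = complex(d2[0] - d1[0], d2[1] - d1[1])
        if zs == 0:
            raise DegenerateGeometryError("source points are coincident")
        z = zd / zs
        a, b = z.real, z.imag
        tx = d1[0] - (a * s1[0] - b * s1[1])
        ty = d1[1] - (b * s1[0] + a * s1[1])
        return cls.from_params(a, b, tx, ty)

    @property
    def rotation_deg(self) -> float:
        return math.degrees(math.atan2(self.m[1, 0], self.m[0, 0]))

    @property
    def scale(self) -> float:
        return math.hypot(self.m[0, 0], self.m[1, 0])

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.m[:, :2].T + self.m[:, 2]

    def __matmul__(self, other: "SimilarityTransform") -> "SimilarityTransform":
        a = np.vstack([self.m, [0.0, 0.0, 1.0]])
        b = np.vstack([other.m, [0.0, 0.0, 1.0]])
        return SimilarityTransform((a @ b)[:2])


def estimate_tilt_transform(lm: LandmarkSet51) -> SimilarityTransform:
    """Transform that levels the outer eye corners P10 and P19.

    The destination points are the eye corners rotated onto the horizontal
    line through their midpoint: a pure rotation about the midpoint, so the
    corner separation (and every other distance) is preserved.
    """
    left, right = lm.eye_corners
    dx, dy = right.x - left.x, right.y - left.y
    if dx == 0.0 and dy == 0.0:
        raise DegenerateGeometryError("outer eye corners coincide; tilt undefined")
    half = math.hypot(dx, dy) / 2.0
    mid = lm.eye_midpoint
    dst = [(mid.x - half, mid.y), (mid.x + half, mid.y)]
    return SimilarityTransform.from_point_pairs([tuple(left), tuple(right)], dst)


def apply_transform(t: SimilarityTransform, lm: LandmarkSet51, *, tilt_corrected: bool | None = None) -> LandmarkSet51:
    """Apply the 2x3 affine product to every landmark."""
    corrected = lm.tilt_corrected if tilt_corrected is None else tilt_corrected
    return LandmarkSet51(t.transform_points(lm.points), source_id=lm.source_id, tilt_corrected=corrected)


def tilt_correct(lm: LandmarkSet51) -> LandmarkSet51:
    """Estimate and apply the tilt correction in one step."""
    t = estimate_tilt_transform(lm)
    return apply_transform(t, lm, tilt_corrected=True)


def rotate_augment(lm: LandmarkSet51, angle_deg: float = 15.0) -> tuple[LandmarkSet51, LandmarkSet51]:
    """Return the +angle and -angle rotations about the eye-corner midpoint.

    Together with the original, this triples the sample count.
    """
    if not angle_deg > 0:
        raise GeometryError("augmentation angle must be strictly positive")
    mid = tuple(lm.eye_midpoint)
    out = []
    for sign in (+1.0, -1.0):
        rot = SimilarityTransform.rotation(math.radians(sign * angle_deg), center=mid)
        out.append(apply_transform(rot, lm, tilt_corrected=False))
    return out[0], out[1]
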