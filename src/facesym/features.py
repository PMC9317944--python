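"""Geometric primitives, the 28 named distances + 2 averages, and the 29
facial-symmetry features with their regional subsets.

Conventions
-----------
* Angles are inclinations relative to the horizontal image axis.  Feature
  angles are folded to the undirected-line range and taken in magnitude, so
  a level pair of homologous points scores 0 and the facial midline scores
  90 regardless of endpoint ordering.
* "Max" features of the form max(r, 1/r) equal 1 exactly when the two
  compared quantities agree; they grow with asymmetry.
* Slope features are signed; a vertical segment raises
  :class:`~facesym.geometry.DegenerateGeometryError` rather than clamping.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import (
    DegenerateGeometryError,
    GeometryError,
    LandmarkSet51,
    MIRROR_INDEX_MAP,
    OUTER_LEFT_EYE,
    OUTER_RIGHT_EYE,
    Point2D,
)

__all__ = [
    "angle_deg",
    "inclination_deg",
    "slope",
    "euclid",
    "perimeter",
    "DistanceDefinition",
    "load_distance_table",
    "default_distance_table",
    "validate_distance_table",
    "DistanceSet",
    "compute_distances",
    "FeatureVector",
    "compute_features",
    "extract_features",
    "RegionSpec",
    "REGIONS",
    "select_region",
    "FEATURE_NAMES",
    "FEATURE_GROUPS",
    "MAX_PAIR_FEATURES",
    "ANGLE_FEATURES",
    "SLOPE_FEATURES",
    "HOMOLOGOUS_PAIRS",
    "SELF_SYMMETRIC_NAMES",
]


# --------------------------------------------------------------------------
# Primitives
# --------------------------------------------------------------------------

def angle_deg(pa, pb) -> float:
    """Inclination of segment pa->pb relative to horizontal, in (-180, 180]."""
    ax, ay = pa
    bx, by = pb
    dx, dy = bx - ax, by - ay
    if dx == 0.0 and dy == 0.0:
        raise DegenerateGeometryError("angle undefined for coincident points")
    ang = math.degrees(math.atan2(dy, dx))
    return 180.0 if ang == -180.0 else ang


def inclination_deg(pa, pb) -> float:
    """Undirected-line inclination folded into (-90, 90]."""
    ang = angle_deg(pa, pb)
    if ang > 90.0:
        ang -= 180.0
    elif ang <= -90.0:
        ang += 180.0
    return ang


def slope(pa, pb) -> float:
    """dy/dx of the segment; vertical segments are a degenerate-geometry error."""
    ax, ay = pa
    bx, by = pb
    if ax == bx:
        raise DegenerateGeometryError("slope undefined for a vertical segment")
    return (ay - by) / (ax - bx)


def euclid(pa, pb) -> float:
    ax, ay = pa
    bx, by = pb
    return math.hypot(ax - bx, ay - by)


def perimeter(shape: Sequence, start: int = 0, end: int | None = None) -> float:
    """Perimeter of the closed polyline shape[start..end] (closing edge included)."""
    pts = list(shape)
    if end is None:
        end = len(pts) - 1
    pts = pts[start : end + 1]
    if len(pts) < 3:
        raise GeometryError("a closed shape needs at least 3 points")
    total = 0.0
    for i in range(len(pts) - 1):
        total += euclid(pts[i], pts[i + 1])
    return total + euclid(pts[0], pts[-1])


# --------------------------------------------------------------------------
# Distance table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceDefinition:
    """One named quantity: an endpoint pair, a closed-shape perimeter, or an
    average eyebrow height relative to the eye-corner line."""

    name: str
    kind: str  # pair | perimeter | brow_height
    points: tuple[int, ...]

    def __post_init__(self):
        if self.kind not in ("pair", "perimeter", "brow_height"):
            raise GeometryError(f"unknown distance kind {self.kind!r} for {self.name}")
        if self.kind == "pair" and len(self.points) != 2:
            raise GeometryError(f"pair distance {self.name} needs exactly 2 points")
        if self.kind == "perimeter" and len(self.points) < 3:
            raise GeometryError(f"perimeter {self.name} needs at least 3 points")
        if any(not (0 <= p < 51) for p in self.points):
            raise GeometryError(f"distance {self.name} references an index outside 0..50")

    def evaluate(self, points: np.ndarray) -> float:
        if self.kind == "pair":
            i, j = self.points
            return euclid(points[i], points[j])
        if self.kind == "perimeter":
            return perimeter([points[i] for i in self.points])
        # brow_height: mean vertical offset of brow points above the line
        # through the outer eye corners (tilt-corrected input assumed level).
        y_ref = (points[OUTER_LEFT_EYE, 1] + points[OUTER_RIGHT_EYE, 1]) / 2.0
        return float(np.mean(y_ref - points[list(self.points), 1]))


#: The 28 pairwise distances, in canonical order.
DISTANCE_NAMES = (
    "A", "Bl", "Br", "C", "D", "E", "F", "G", "H", "I", "J", "K",
    "Nl", "Nr", "Ol", "Or", "Pl", "Pu", "Ql", "Qu",
    "R", "S", "T", "U", "Vl", "Vr", "W", "X",
)
AVERAGE_NAMES = ("L", "M")
PERIMETER_NAMES = ("Wl", "Wr")
ALL_QUANTITY_NAMES = DISTANCE_NAMES + AVERAGE_NAMES + PERIMETER_NAMES

#: Left/right homologous quantity pairs under midline reflection.
HOMOLOGOUS_PAIRS = (
    ("Bl", "Br"), ("D", "E"), ("F", "G"), ("H", "I"), ("J", "K"),
    ("Nl", "Or"), ("Nr", "Ol"), ("Pl", "Ql"), ("Pu", "Qu"),
    ("R", "S"), ("T", "U"), ("Vl", "Vr"), ("L", "M"), ("Wl", "Wr"),
)
#: Quantities whose endpoint sets map onto themselves under reflection.
SELF_SYMMETRIC_NAMES = ("A", "C", "W", "X")


def load_distance_table(path) -> dict[str, DistanceDefinition]:
    """Load the distance-definition file (CSV: name, kind, space-separated points)."""
    table: dict[str, DistanceDefinition] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            name = rec["name"].strip()
            pts = tuple(int(t) for t in rec["points"].split())
            table[name] = DistanceDefinition(name, rec["kind"].strip(), pts)
    validate_distance_table(table)
    return table


def validate_distance_table(table: Mapping[str, DistanceDefinition]) -> None:
    """Check completeness and left/right homology of a distance table."""
    missing = [n for n in ALL_QUANTITY_NAMES if n not in table]
    if missing:
        raise GeometryError(f"distance table is missing definitions for {missing}")
    for left, right in HOMOLOGOUS_PAIRS:
        dl, dr = table[left], table[right]
        if dl.kind != dr.kind:
            raise GeometryError(f"{left}/{right} must share a kind")
        mirrored = frozenset(int(MIRROR_INDEX_MAP[p]) for p in dl.points)
        if mirrored != frozenset(dr.points):
            raise GeometryError(
                f"{left} and {right} are not mirror-homologous: "
                f"{sorted(mirrored)} vs {sorted(dr.points)}"
            )
    for name in SELF_SYMMETRIC_NAMES:
        pts = frozenset(table[name].points)
        if frozenset(int(MIRROR_INDEX_MAP[p]) for p in pts) != pts:
            raise GeometryError(f"{name} must be symmetric about the midline")


_DEFAULT_TABLE: dict[str, DistanceDefinition] | None = None


def default_distance_table() -> dict[str, DistanceDefinition]:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        ref = resources.files("facesym.data") / "distances.csv"
        with resources.as_file(ref) as p:
            _DEFAULT_TABLE = load_distance_table(p)
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class DistanceSet:
    """The 28 named distances, the two average brow heights (L, M), and the
    two outer-lip half-perimeters (Wl, Wr)."""

    values: Mapping[str, float]

    def __post_init__(self):
        missing = [n for n in ALL_QUANTITY_NAMES if n not in self.values]
        if missing:
            raise GeometryError(f"DistanceSet missing {missing}")
        for name in DISTANCE_NAMES + PERIMETER_NAMES:
            if self.values[name] < 0:
                raise GeometryError(f"distance {name} is negative")
        for name in ("A", "W"):
            if not self.values[name] > 0:
                raise DegenerateGeometryError(f"normalizing distance {name} must be positive")

    def __getattr__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def distance_names(self) -> tuple[str, ...]:
        return DISTANCE_NAMES

    @property
    def average_names(self) -> tuple[str, ...]:
        return AVERAGE_NAMES


def compute_distances(
    lm: LandmarkSet51,
    table: Mapping[str, DistanceDefinition] | None = None,
) -> DistanceSet:
    """Evaluate every named quantity of the distance table on a landmark set."""
    if table is None:
        table = default_distance_table()
    else:
        validate_distance_table(table)
    vals = {name: table[name].evaluate(lm.points) for name in ALL_QUANTITY_NAMES}
    return DistanceSet(vals)


# --------------------------------------------------------------------------
# The 29 symmetry features
# --------------------------------------------------------------------------

FEATURE_NAMES = tuple(f"f{i}" for i in range(29))

#: Facial-region group of each feature, in f-order.
FEATURE_GROUPS = (
    "Eyebrows", "Eyebrows", "Eyebrows", "Eyebrows", "Eyebrows", "Eyebrows", "Eyebrows",
    "Eyes", "Eyes", "Eyes", "Eyes", "Eyes", "Eyes", "Eyes",
    "Mouth", "Mouth", "Mouth", "Mouth", "Mouth", "Mouth", "Mouth", "Mouth",
    "Nose",
    "Combined", "Combined", "Combined", "Combined", "Combined", "Combined",
)

ANGLE_FEATURES = (0, 1, 2, 7, 14, 22, 23)
SLOPE_FEATURES = (4, 5, 6)
#: Max-type features of the form max(r, 1/r); exactly 1 on a symmetric face.
MAX_PAIR_FEATURES = (3, 8, 9, 10, 11, 12, 13, 15, 16, 17, 24)
#: Max-type features sharing a global denominator (A or W); equal left/right
#: operands on a symmetric face, but not pinned to 1.
MAX_SHARED_FEATURES = (18, 19, 20, 21, 25, 26)
RATIO_FEATURES = (27, 28)


def _max_pair(num: float, den: float, feature: str) -> float:
    if num <= 0 or den <= 0:
        raise DegenerateGeometryError(f"{feature}: ratio operands must be positive")
    r = num / den
    return max(r, 1.0 / r)


def _checked_div(num: float, den: float, feature: str) -> float:
    if den <= 0:
        raise DegenerateGeometryError(f"{feature}: zero or negative denominator")
    return num / den


def compute_features(
    ds: DistanceSet,
    lm: LandmarkSet51,
    *,
    source_id: str | None = None,
) -> "FeatureVector":
    """Evaluate the 29 symmetry features from a distance set and landmarks."""
    p = lm.points

    def ang(i: int, j: int) -> float:
        return abs(inclination_deg(p[i], p[j]))

    n_avg = (ds.Nl + ds.Nr) / 2.0
    o_avg = (ds.Ol + ds.Or) / 2.0

    f = np.empty(29, dtype=float)
    f[0] = ang(0, 9)
    f[1] = ang(2, 7)
    f[2] = ang(4, 5)
    f[3] = _max_pair(ds.L, ds.M, "f3")
    f[4] = slope(p[0], p[9])
    f[5] = slope(p[2], p[7])
    f[6] = slope(p[4], p[5])
    f[7] = ang(10, 19)
    f[8] = _max_pair(ds.Bl, ds.Br, "f8")
    f[9] = _max_pair(ds.D, ds.E, "f9")
    f[10] = _max_pair(ds.H, ds.I, "f10")
    f[11] = _max_pair(n_avg, o_avg, "f11")
    f[12] = _max_pair(ds.Nl, ds.Or, "f12")
    f[13] = _max_pair(ds.Nr, ds.Ol, "f13")
    f[14] = ang(28, 34)
    f[15] = _max_pair(ds.F, ds.G, "f15")
    f[16] = _max_pair(ds.Pl, ds.Ql, "f16")
    f[17] = _max_pair(ds.Pu, ds.Qu, "f17")
    f[18] = max(_checked_div(ds.Vl, ds.A, "f18"), _checked_div(ds.Vr, ds.A, "f18"))
    f[19] = max(_checked_div(ds.Pl, ds.W, "f19"), _checked_div(ds.Ql, ds.W, "f19"))
    f[20] = max(_checked_div(ds.Pu, ds.W, "f20"), _checked_div(ds.Qu, ds.W, "f20"))
    f[21] = max(_checked_div(ds.Wl, ds.W, "f21"), _checked_div(ds.Wr, ds.W, "f21"))
    f[22] = ang(23, 27)
    f[23] = ang(22, 37)
    f[24] = _max_pair(ds.J, ds.K, "f24")
    f[25] = max(_checked_div(ds.T, ds.A, "f25"), _checked_div(ds.U, ds.A, "f25"))
    f[26] = max(_checked_div(ds.R, ds.A, "f26"), _checked_div(ds.S, ds.A, "f26"))
    f[27] = _checked_div(ds.C, ds.A, "f27")
    f[28] = _checked_div(ds.X, ds.A, "f28")

    sid = lm.source_id if source_id is None else source_id
    return FeatureVector(values=f, region_tag="face", source_id=sid)


def extract_features(
    lm: LandmarkSet51,
    *,
    region: "str | RegionSpec" = "face",
    table: Mapping[str, DistanceDefinition] | None = None,
) -> "FeatureVector":
    """Distances + features (+ optional regional projection) in one call."""
    ds = compute_distances(lm, table)
    fv = compute_features(ds, lm)
    if isinstance(region, str) and region == "face":
        return fv
    return select_region(fv, region)


# --------------------------------------------------------------------------
# Regional subsets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    name: str
    indices: tuple[int, ...]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(FEATURE_NAMES[i] for i in self.indices)


def _eyes_indices() -> tuple[int, ...]:
    # Eyebrows + Eyes + Nose groups, plus Combined f23 and f25-f27.
    base = [i for i, g in enumerate(FEATURE_GROUPS) if g in ("Eyebrows", "Eyes", "Nose")]
    return tuple(sorted(base + [23, 25, 26, 27]))


def _mouth_indices() -> tuple[int, ...]:
    # Everything except the Eyebrows and Eyes groups.
    return tuple(i for i, g in enumerate(FEATURE_GROUPS) if g not in ("Eyebrows", "Eyes"))


REGIONS: dict[str, RegionSpec] = {
    "face": RegionSpec("face", tuple(range(29))),
    "eyes": RegionSpec("eyes", _eyes_indices()),
    "mouth": RegionSpec("mouth", _mouth_indices()),
}


@dataclass(frozen=True)
class FeatureVector:
    """Feature values in f-order (full 29 or a regional projection)."""

    values: np.ndarray
    region_tag: str = "face"
    source_id: str = ""

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        expected = len(REGIONS[self.region_tag].indices) if self.region_tag in REGIONS else None
        if expected is not None and vals.shape != (expected,):
            raise GeometryError(
                f"region {self.region_tag!r} expects {expected} values, got {vals.shape}"
            )
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return REGIONS[self.region_tag].feature_names

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.values.tolist()))


def select_region(fv: FeatureVector, region: str | RegionSpec) -> FeatureVector:
    """Project a full feature vector onto a regional subset (order preserved)."""
    if isinstance(region, str):
        try:
            region = REGIONS[region]
        except KeyError:
            raise GeometryError(f"unknown region {region!r}; expected face/eyes/mouth") from None
    if fv.region_tag != "face":
        raise GeometryError("regional selection requires a full 29-feature vector")
    return FeatureVector(fv.values[list(region.indices)], region_tag=region.name, source_id=fv.source_id)
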