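"""Synthetic labeled landmark data: a mirror-symmetric face template with
parameterized unilateral droop, Gaussian jitter and global pose.

The generator emulates three classes — healthy (SL0), slight (SL1) and
strong (SL2) unilateral droop — so the whole feature + classification
pipeline is testable without any real face database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    GeometryError,
    LandmarkSet51,
    MIRROR_INDEX_MAP,
    SimilarityTransform,
    apply_transform,
)

__all__ = [
    "FaceTemplate",
    "PalsyPerturbation",
    "SeverityProfile",
    "SyntheticConfig",
    "make_template",
    "apply_palsy",
    "apply_pose",
    "generate_subjects",
    "generate_dataset",
    "SEVERITY_LABELS",
]

SEVERITY_LABELS = ("SL0", "SL1", "SL2")

# Canonical symmetric layout: midline at x = 0, outer eye corners at
# (-50, 0) and (50, 0), y grows downward.  Scaled by interocular/100.
_TEMPLATE_LOCAL = np.array([
    # eyebrows, left P0-P4 (outer -> inner), right P5-P9 (inner -> outer)
    (-58.0, -26.0), (-50.0, -28.0), (-42.0, -29.0), (-34.0, -28.0), (-18.0, -26.0),
    (18.0, -26.0), (34.0, -28.0), (42.0, -29.0), (50.0, -28.0), (58.0, -26.0),
    # left eye P10-P15: outer corner, upper lid x2, inner corner, lower lid x2
    (-50.0, 0.0), (-42.0, -4.0), (-34.0, -4.0), (-26.0, 0.0), (-34.0, 4.0), (-42.0, 4.0),
    # right eye P16-P21: inner corner, upper lid x2, outer corner, lower lid x2
    (26.0, 0.0), (34.0, -4.0), (42.0, -4.0), (50.0, 0.0), (42.0, 4.0), (34.0, 4.0),
    # nose bridge top P22
    (0.0, 0.0),
    # nose bottom row P23-P27
    (-12.0, 34.0), (-6.0, 36.0), (0.0, 37.0), (6.0, 36.0), (12.0, 34.0),
    # outer lip P28-P39 (left corner, upper arc, right corner, lower arc);
    # corners sit low (near the lower-lip line) so a downward corner droop
    # moves them away from every fixed midline point from the start
    (-22.0, 56.0), (-14.0, 46.0), (-6.0, 44.0), (0.0, 45.0), (6.0, 44.0),
    (14.0, 46.0), (22.0, 56.0), (14.0, 55.0), (6.0, 57.0), (0.0, 58.0),
    (-6.0, 57.0), (-14.0, 55.0),
    # inner lip P40-P47
    (-18.0, 56.0), (-6.0, 48.0), (0.0, 49.0), (6.0, 48.0), (18.0, 56.0),
    (6.0, 53.0), (0.0, 54.0), (-6.0, 53.0),
    # nose bridge P48-P50
    (0.0, 10.0), (0.0, 18.0), (0.0, 26.0),
])


@dataclass(frozen=True)
class FaceTemplate:
    """A landmark set that is exactly mirror-symmetric about a vertical line."""

    landmarks: LandmarkSet51
    midline_x: float

    _TOL = 1e-9

    def __post_init__(self):
        pts = self.landmarks.points
        mirrored = pts[MIRROR_INDEX_MAP].copy()
        mirrored[:, 0] = 2.0 * self.midline_x - mirrored[:, 0]
        if not np.allclose(pts, mirrored, atol=self._TOL):
            raise GeometryError("template is not mirror-symmetric about midline_x")


def make_template(scale: float = 100.0, center: tuple[float, float] = (100.0, 100.0)) -> FaceTemplate:
    """Symmetric 51-point layout with the given interocular distance (px).

    ``center`` places the eye-corner midpoint in image coordinates.
    """
    if not scale > 0:
        raise GeometryError("template scale must be positive")
    pts = _TEMPLATE_LOCAL * (scale / 100.0)
    pts = pts + np.asarray(center, dtype=float)
    lm = LandmarkSet51(pts, source_id="template", tilt_corrected=True)
    return FaceTemplate(landmarks=lm, midline_x=float(center[0]))


# --------------------------------------------------------------------------
# Unilateral droop
# --------------------------------------------------------------------------

# Per-point droop weights on the image-left side, one profile per region.
# Values are fractions of the region's droop magnitude applied along +y
# (downward); attenuation grows toward the midline.
_BROW_WEIGHTS = {0: 1.0, 1: 0.9, 2: 0.75, 3: 0.55, 4: 0.35}
# Upper-lid weights exceed lower-lid weights so the aperture narrows with
# droop, but by < 0.4 so the lids never cross within a 20 px magnitude.
_EYE_WEIGHTS = {10: 0.45, 11: 0.55, 12: 0.5, 13: 0.3, 14: 0.25, 15: 0.3}
_MOUTH_WEIGHTS = {
    28: 1.0, 29: 0.8, 30: 0.5, 38: 0.55, 39: 0.8,   # outer lip, left half
    40: 0.9, 41: 0.5, 47: 0.55,                      # inner lip, left half
}
#: Lateral pull (toward image-left) as a fraction of the mouth magnitude.
_MOUTH_LATERAL = {28: 0.2, 29: 0.12, 39: 0.12, 40: 0.16}


@dataclass(frozen=True)
class PalsyPerturbation:
    """Unilateral droop magnitudes (pixels) per facial region."""

    side: str = "left"  # image-left or image-right
    brow: float = 0.0
    eye: float = 0.0
    mouth: float = 0.0
    severity_class: str | None = None

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise GeometryError("side must be 'left' or 'right'")
        if min(self.brow, self.eye, self.mouth) < 0:
            raise GeometryError("droop magnitudes must be nonnegative")


def _droop_field(p: PalsyPerturbation) -> np.ndarray:
    """(51, 2) displacement for an image-left droop; mirrored for 'right'."""
    disp = np.zeros((51, 2))
    for idx, w in _BROW_WEIGHTS.items():
        disp[idx, 1] += w * p.brow
    for idx, w in _EYE_WEIGHTS.items():
        disp[idx, 1] += w * p.eye
    for idx, w in _MOUTH_WEIGHTS.items():
        disp[idx, 1] += w * p.mouth
    for idx, w in _MOUTH_LATERAL.items():
        disp[idx, 0] -= w * p.mouth
    if p.side == "right":
        mirrored = disp[MIRROR_INDEX_MAP].copy()
        mirrored[:, 0] *= -1.0
        disp = mirrored
    return disp


def apply_palsy(
    t: FaceTemplate,
    p: PalsyPerturbation,
    rng: np.random.Generator | None = None,
    jitter_sd: float = 0.0,
) -> LandmarkSet51:
    """Displace one side of the template downward/outward; optionally add
    isotropic Gaussian jitter to every point."""
    pts = t.landmarks.points + _droop_field(p)
    if jitter_sd > 0:
        if rng is None:
            raise GeometryError("jitter requested but no rng supplied")
        pts = pts + rng.normal(0.0, jitter_sd, size=pts.shape)
    return LandmarkSet51(pts, source_id=t.landmarks.source_id, tilt_corrected=False)


def apply_pose(
    lm: LandmarkSet51,
    rotation_deg: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
    scale: float = 1.0,
) -> LandmarkSet51:
    """Global similarity pose: rotate about the eye midpoint, scale, translate."""
    if not scale > 0:
        raise GeometryError("pose scale must be positive")
    rot = SimilarityTransform.rotation(
        math.radians(rotation_deg), center=tuple(lm.eye_midpoint), scale=scale
    )
    posed = apply_transform(rot, lm, tilt_corrected=False)
    pts = posed.points + np.asarray(translation, dtype=float)
    return LandmarkSet51(pts, source_id=lm.source_id, tilt_corrected=False)


# --------------------------------------------------------------------------
# Dataset generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SeverityProfile:
    """Droop magnitude range (pixels at interocular 100) and per-region mix."""

    magnitude: tuple[float, float]
    brow_mix: float = 0.6
    eye_mix: float = 0.8
    mouth_mix: float = 1.0


DEFAULT_PROFILES: dict[str, SeverityProfile] = {
    "SL1": SeverityProfile(magnitude=(3.0, 6.0)),
    "SL2": SeverityProfile(magnitude=(8.0, 16.0)),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything the generator needs; the seed fixes the full stream."""

    n_per_class: int = 20
    images_per_subject: int = 20
    interocular: float = 100.0
    jitter_sd: float = 0.5
    rotation_deg: float = 10.0
    translation_px: float = 20.0
    scale_range: tuple[float, float] = (0.8, 1.25)
    rng_seed: int = 0
    classes: tuple[str, ...] = SEVERITY_LABELS
    profiles: dict[str, SeverityProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )

    def __post_init__(self):
        if self.n_per_class < 1:
            raise GeometryError("n_per_class must be >= 1")
        if self.jitter_sd < 0:
            raise GeometryError("jitter_sd must be >= 0")
        for c in self.classes:
            if c not in SEVERITY_LABELS:
                raise GeometryError(f"unknown class label {c!r}")
            if c != "SL0" and c not in self.profiles:
                raise GeometryError(f"class {c} has no severity profile")


def _subject_perturbation(
    cfg: SyntheticConfig, label: str, rng: np.random.Generator
) -> PalsyPerturbation:
    if label == "SL0":
        return PalsyPerturbation(side="left", severity_class="SL0")
    prof = cfg.profiles[label]
    mag = rng.uniform(*prof.magnitude) * (cfg.interocular / 100.0)
    side = "left" if rng.random() < 0.5 else "right"
    return PalsyPerturbation(
        side=side,
        brow=mag * prof.brow_mix,
        eye=mag * prof.eye_mix,
        mouth=mag * prof.mouth_mix,
        severity_class=label,
    )


def generate_subjects(cfg: SyntheticConfig):
    """Deterministically generate per-subject landmark samples.

    Returns a list of :class:`facesym.evaluate.SubjectRecord`, each holding
    ``cfg.images_per_subject`` posed, jittered landmark sets.  One subject ==
    one severity draw (side + magnitude); images vary by jitter and pose.
    """
    from .evaluate import SubjectRecord  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.rng_seed)
    template = make_template(scale=cfg.interocular)
    subjects = []
    for label in cfg.classes:
        for s in range(cfg.n_per_class):
            sid = f"{label}_s{s:03d}"
            pert = _subject_perturbation(cfg, label, rng)
            samples = []
            for k in range(cfg.images_per_subject):
                lm = apply_palsy(template, pert, rng=rng, jitter_sd=cfg.jitter_sd)
                lm = apply_pose(
                    lm,
                    rotation_deg=rng.uniform(-cfg.rotation_deg, cfg.rotation_deg),
                    translation=tuple(rng.uniform(-cfg.translation_px, cfg.translation_px, 2)),
                    scale=rng.uniform(*cfg.scale_range),
                )
                samples.append(
                    LandmarkSet51(lm.points, source_id=f"{sid}_i{k:03d}", tilt_corrected=False)
                )
            subjects.append(SubjectRecord(subject_id=sid, severity=label, samples=samples))
    return subjects


def generate_dataset(cfg: SyntheticConfig, *, task: str = "three_level", region: str = "face"):
    """Generate subjects, tilt-correct, extract features and label them.

    A thin convenience over :func:`generate_subjects` +
    :func:`facesym.evaluate.assemble_experiment`.
    """
    from .evaluate import assemble_experiment

    subjects = generate_subjects(cfg)
    return assemble_experiment(subjects, task=task, region=region)
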