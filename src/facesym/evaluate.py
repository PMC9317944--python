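"""Dataset assembly, classifier presets, repeated stratified k-fold
cross-validation and the seven confusion-matrix statistics.

The default protocol mirrors the evaluation design the feature set was
validated with: stratified 5-fold CV repeated 10 times, splitting by image
(samples of one subject may land in both train and test); a group-by-subject
mode is available and logs no leakage warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.svm import SVC

from .features import REGIONS, FeatureVector, extract_features, select_region
from .geometry import GeometryError, LandmarkSet51, rotate_augment, tilt_correct

log = logging.getLogger(__name__)

__all__ = [
    "LabeledSample",
    "LabeledDataset",
    "SubjectRecord",
    "ClassifierConfig",
    "ConfusionMatrix",
    "Metrics",
    "MetricsReport",
    "EvaluationError",
    "load_presets",
    "get_preset",
    "build_estimator",
    "train_predict",
    "compute_metrics",
    "repeated_kfold",
    "assemble_experiment",
    "CLASSIFIER_FAMILIES",
    "TASKS",
]

CLASSIFIER_FAMILIES = ("MLP", "SVM", "KNN", "MNLR")
TASKS = ("detect", "two_level", "three_level")

METRIC_NAMES = ("Acc", "Rec", "Prec", "F1s", "TNR", "FNR", "FPR")


class EvaluationError(ValueError):
    """Invalid evaluation configuration or degenerate dataset."""


# --------------------------------------------------------------------------
# Data containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectRecord:
    """All landmark samples of one (synthetic or real) subject."""

    subject_id: str
    severity: str  # SL0 | SL1 | SL2
    samples: tuple[LandmarkSet51, ...]

    def __post_init__(self):
        object.__setattr__(self, "samples", tuple(self.samples))
        if self.severity not in ("SL0", "SL1", "SL2"):
            raise EvaluationError(f"unknown severity {self.severity!r}")


@dataclass(frozen=True)
class LabeledSample:
    features: FeatureVector
    label: str
    subject_id: str
    augmented_from: str | None = None


@dataclass(frozen=True)
class LabeledDataset:
    samples: tuple[LabeledSample, ...]
    region_tag: str = "face"
    task: str = "detect"

    def __post_init__(self):
        object.__setattr__(self, "samples", tuple(self.samples))
        for s in self.samples:
            if s.features.region_tag != self.region_tag:
                raise EvaluationError("sample region does not match dataset region")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def X(self) -> np.ndarray:
        return np.stack([s.features.values for s in self.samples])

    @property
    def y(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])

    @property
    def subject_ids(self) -> np.ndarray:
        return np.array([s.subject_id for s in self.samples])

    @property
    def label_set(self) -> tuple[str, ...]:
        return tuple(sorted(set(s.label for s in self.samples)))

    @property
    def feature_names(self) -> tuple[str, ...]:
        return REGIONS[self.region_tag].feature_names

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


# --------------------------------------------------------------------------
# Classifier presets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    """One classifier family plus its complete parameter map.

    MLP: L (learning rate), M (momentum), H (hidden units), N (epochs),
    S (seed).  SVM: C, G, kernel.  KNN: k, distance.  MNLR: R (ridge).
    """

    family: str
    parameters: Mapping[str, object]

    _REQUIRED = {
        "MLP": ("L", "M", "H", "N", "S"),
        "SVM": ("C", "G", "kernel"),
        "KNN": ("k", "distance"),
        "MNLR": ("R",),
    }

    def __post_init__(self):
        if self.family not in CLASSIFIER_FAMILIES:
            raise EvaluationError(f"unknown classifier family {self.family!r}")
        missing = [k for k in self._REQUIRED[self.family] if k not in self.parameters]
        if missing:
            raise EvaluationError(f"{self.family} preset missing parameters {missing}")
        object.__setattr__(self, "parameters", dict(self.parameters))


_PRESETS: dict | None = None


def load_presets() -> dict[str, dict[str, ClassifierConfig]]:
    """Shipped presets keyed by experiment name, then classifier family."""
    global _PRESETS
    if _PRESETS is None:
        ref = resources.files("facesym.data") / "presets.yaml"
        raw = yaml.safe_load(ref.read_text())
        _PRESETS = {
            exp: {fam: ClassifierConfig(fam, params) for fam, params in fams.items()}
            for exp, fams in raw.items()
        }
    return _PRESETS


def get_preset(experiment: str, family: str) -> ClassifierConfig:
    presets = load_presets()
    try:
        return presets[experiment][family]
    except KeyError:
        raise EvaluationError(
            f"no preset for experiment={experiment!r}, family={family!r}"
        ) from None


def build_estimator(cfg: ClassifierConfig, *, max_epochs: int | None = None) -> Pipeline:
    """Instantiate the scikit-learn backend for a preset.

    ``max_epochs`` caps MLP training epochs below the preset's N for
    compute-budgeted runs; it never raises them.
    """
    p = cfg.parameters
    if cfg.family == "MLP":
        epochs = int(p["N"])
        if max_epochs is not None:
            epochs = min(epochs, int(max_epochs))
        est = MLPClassifier(
            hidden_layer_sizes=(int(p["H"]),),
            activation="logistic",
            solver="sgd",
            learning_rate="constant",
            learning_rate_init=float(p["L"]),
            momentum=float(p["M"]),
            nesterovs_momentum=False,
            max_iter=epochs,
            n_iter_no_change=epochs,  # train the full epoch budget
            tol=0.0,
            random_state=int(p["S"]),
        )
        scaler = StandardScaler()
    elif cfg.family == "SVM":
        if str(p["kernel"]).lower() != "rbf":
            raise EvaluationError("only the RBF kernel is configured")
        est = SVC(C=float(p["C"]), gamma=float(p["G"]), kernel="rbf")
        scaler = StandardScaler()
    elif cfg.family == "KNN":
        est = KNeighborsClassifier(n_neighbors=int(p["k"]), metric=str(p["distance"]))
        scaler = MinMaxScaler()
    else:  # MNLR
        ridge = float(p["R"])
        if ridge <= 0:
            raise EvaluationError("MNLR ridge must be positive")
        est = LogisticRegression(C=1.0 / ridge, max_iter=2000)
        scaler = StandardScaler()
    return Pipeline([("scale", scaler), ("clf", est)])


def train_predict(
    cfg: ClassifierConfig,
    train: LabeledDataset,
    test: LabeledDataset,
    *,
    max_epochs: int | None = None,
) -> np.ndarray:
    """Fit the configured classifier on ``train`` and label ``test``."""
    if train.region_tag != test.region_tag:
        raise EvaluationError("train/test feature dimensionality mismatch")
    if not set(test.label_set) <= set(train.label_set):
        raise EvaluationError("test labels outside the training label set")
    model = build_estimator(cfg, max_epochs=max_epochs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(train.X, train.y)
    return model.predict(test.X)


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """Count matrix with counts[i, j] = truth i predicted j."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if c.shape != (k, k):
            raise EvaluationError(f"confusion matrix must be {k}x{k}")
        if (c < 0).any():
            raise EvaluationError("confusion counts must be nonnegative")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "labels", tuple(self.labels))

    @classmethod
    def binary(cls, tp: int, tn: int, fp: int, fn: int, labels=("0", "1")) -> "ConfusionMatrix":
        return cls(np.array([[tn, fp], [fn, tp]]), labels)

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels: Sequence[str]) -> "ConfusionMatrix":
        idx = {l: i for i, l in enumerate(labels)}
        c = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            c[idx[str(t)], idx[str(p)]] += 1
        return cls(c, tuple(labels))

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise EvaluationError("cannot add confusion matrices with different labels")
        return ConfusionMatrix(self.counts + other.counts, self.labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def is_binary(self) -> bool:
        return len(self.labels) == 2

    def binary_counts(self) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) with the second label as the positive class."""
        if not self.is_binary:
            raise EvaluationError("binary counts require a 2-class matrix")
        tn, fp = self.counts[0]
        fn, tp = self.counts[1]
        return int(tp), int(tn), int(fp), int(fn)


@dataclass(frozen=True)
class Metrics:
    """The seven statistics: Acc, Rec, Prec, F1s, TNR, FNR, FPR."""

    Acc: float
    Rec: float
    Prec: float
    F1s: float
    TNR: float
    FNR: float
    FPR: float

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in METRIC_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in METRIC_NAMES])


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting NaN", RuntimeWarning)
        return float("nan")
    return num / den


def _binary_metrics(tp: int, tn: int, fp: int, fn: int) -> Metrics:
    return Metrics(
        Acc=_safe_div(tp + tn, tp + tn + fp + fn, "Acc"),
        Rec=_safe_div(tp, tp + fn, "Rec"),
        Prec=_safe_div(tp, tp + fp, "Prec"),
        F1s=_safe_div(2 * tp, 2 * tp + fp + fn, "F1s"),
        TNR=_safe_div(tn, tn + fp, "TNR"),
        FNR=_safe_div(fn, fn + tp, "FNR"),
        FPR=_safe_div(fp, fp + tn, "FPR"),
    )


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Seven statistics from a confusion matrix.

    Binary matrices use the literal formulas with the second label positive.
    Multi-class matrices report accuracy as trace/total and the remaining
    statistics macro-averaged one-vs-rest (an extension beyond the binary
    definitions, labeled as such in reports).
    """
    if cm.total == 0:
        raise EvaluationError("cannot compute metrics from an all-zero matrix")
    if cm.is_binary:
        tp, tn, fp, fn = cm.binary_counts()
        return _binary_metrics(tp, tn, fp, fn)
    per_class = []
    for i in range(len(cm.labels)):
        tp = int(cm.counts[i, i])
        fn = int(cm.counts[i].sum()) - tp
        fp = int(cm.counts[:, i].sum()) - tp
        tn = cm.total - tp - fn - fp
        per_class.append(_binary_metrics(tp, tn, fp, fn).as_array())
    macro = np.nanmean(np.stack(per_class), axis=0)
    vals = dict(zip(METRIC_NAMES, macro))
    vals["Acc"] = float(np.trace(cm.counts)) / cm.total
    return Metrics(**vals)


@dataclass(frozen=True)
class MetricsReport:
    """Per-repeat metrics plus mean and standard deviation across repeats.

    ``fold_metrics`` additionally breaks each repeat down by fold, and
    ``std_over_folds`` gives the spread across all k*repeats folds, since a
    reported +/- may refer to either population.
    """

    repeat_metrics: tuple[Metrics, ...]
    fold_metrics: tuple[tuple[Metrics, ...], ...]
    confusion: ConfusionMatrix  # accumulated over all repeats

    @property
    def mean(self) -> Metrics:
        arr = np.stack([m.as_array() for m in self.repeat_metrics])
        return Metrics(**dict(zip(METRIC_NAMES, np.nanmean(arr, axis=0))))

    @property
    def std(self) -> Metrics:
        arr = np.stack([m.as_array() for m in self.repeat_metrics])
        return Metrics(**dict(zip(METRIC_NAMES, np.nanstd(arr, axis=0, ddof=1) if len(arr) > 1 else np.zeros(arr.shape[1]))))

    @property
    def std_over_folds(self) -> Metrics:
        arr = np.stack([m.as_array() for rep in self.fold_metrics for m in rep])
        return Metrics(**dict(zip(METRIC_NAMES, np.nanstd(arr, axis=0, ddof=1) if len(arr) > 1 else np.zeros(arr.shape[1]))))

    def summary(self) -> dict:
        return {
            "mean": self.mean.as_dict(),
            "std_over_repeats": self.std.as_dict(),
            "std_over_folds": self.std_over_folds.as_dict(),
            "n_repeats": len(self.repeat_metrics),
            "confusion": self.confusion.counts.tolist(),
            "labels": list(self.confusion.labels),
        }


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------

def _subset(ds: LabeledDataset, idx: np.ndarray) -> LabeledDataset:
    return LabeledDataset(
        tuple(ds.samples[i] for i in idx), region_tag=ds.region_tag, task=ds.task
    )


def repeated_kfold(
    ds: LabeledDataset,
    cfg: ClassifierConfig,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    *,
    max_epochs: int | None = None,
    group_by_subject: bool = False,
) -> MetricsReport:
    """Stratified k-fold CV repeated ``repeats`` times.

    Each repeat reshuffles with seed ``seed + repeat`` and tests every sample
    exactly once; confusion counts are accumulated over the k folds of a
    repeat before metrics are taken, then summarized as mean +/- std across
    repeats.
    """
    if k < 2:
        raise EvaluationError("k must be >= 2")
    labels = ds.label_set
    counts = ds.class_counts()
    small = [l for l, c in counts.items() if c < k]
    if small:
        raise EvaluationError(f"classes {small} have fewer members than k={k}")
    if not group_by_subject and len(set(ds.subject_ids)) < len(ds):
        log.info(
            "image-wise splitting: samples of one subject may appear in both "
            "train and test folds (use group_by_subject=True to prevent this)"
        )

    y = ds.y
    groups = ds.subject_ids if group_by_subject else None
    repeat_metrics = []
    fold_metrics = []
    grand = ConfusionMatrix(np.zeros((len(labels), len(labels)), int), labels)
    for rep in range(repeats):
        splitter_cls = StratifiedGroupKFold if group_by_subject else StratifiedKFold
        splitter = splitter_cls(n_splits=k, shuffle=True, random_state=seed + rep)
        rep_cm = ConfusionMatrix(np.zeros((len(labels), len(labels)), int), labels)
        per_fold = []
        for train_idx, test_idx in splitter.split(ds.X, y, groups):
            pred = train_predict(
                cfg, _subset(ds, train_idx), _subset(ds, test_idx), max_epochs=max_epochs
            )
            fold_cm = ConfusionMatrix.from_predictions(y[test_idx], pred, labels)
            rep_cm = rep_cm + fold_cm
            per_fold.append(compute_metrics(fold_cm))
        if rep_cm.total != len(ds):
            raise EvaluationError("folds did not cover the dataset exactly once")
        repeat_metrics.append(compute_metrics(rep_cm))
        fold_metrics.append(tuple(per_fold))
        grand = grand + rep_cm
    return MetricsReport(tuple(repeat_metrics), tuple(fold_metrics), grand)


# --------------------------------------------------------------------------
# Experiment assembly
# --------------------------------------------------------------------------

def _task_label(task: str, severity: str) -> str | None:
    """Map a severity to the task's label, or None to drop the sample."""
    if task == "detect":
        return "0" if severity == "SL0" else "1"
    if task == "two_level":
        return None if severity == "SL0" else severity
    if task == "three_level":
        return severity
    raise EvaluationError(f"unknown task {task!r}; expected one of {TASKS}")


def assemble_experiment(
    sources: Iterable[SubjectRecord],
    task: str,
    region: str = "face",
    per_subject_cap: int | None = None,
    augment: bool = False,
    augment_angle: float = 15.0,
) -> LabeledDataset:
    """Build a labeled feature dataset from per-subject landmark records.

    Applies, in order: the task's label collapse (dropping severities the
    task excludes), the per-subject image cap, optional two-opposite-rotations
    augmentation (tripling the count), tilt correction, feature extraction
    and regional projection.
    """
    if region not in REGIONS:
        raise EvaluationError(f"unknown region {region!r}")
    samples: list[LabeledSample] = []
    for rec in sources:
        label = _task_label(task, rec.severity)
        if label is None:
            continue
        lms = rec.samples[:per_subject_cap] if per_subject_cap else rec.samples
        for lm in lms:
            variants = [(lm, None)]
            if augment:
                plus, minus = rotate_augment(lm, augment_angle)
                variants += [(plus, lm.source_id), (minus, lm.source_id)]
            for v_lm, parent in variants:
                fv = extract_features(tilt_correct(v_lm), region=region)
                samples.append(
                    LabeledSample(
                        features=fv,
                        label=label,
                        subject_id=rec.subject_id,
                        augmented_from=parent,
                    )
                )
    ds = LabeledDataset(tuple(samples), region_tag=region, task=task)
    expected = {"detect": 2, "two_level": 2, "three_level": 3}[task]
    if len(ds) == 0 or len(ds.label_set) < expected:
        raise EvaluationError(
            f"task {task!r} needs {expected} populated classes, got {ds.class_counts()}"
        )
    return ds
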