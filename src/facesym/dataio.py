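"""Readers and writers: landmark CSV/JSON, feature CSV, dense ARFF export."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluate import EvaluationError, LabeledDataset, LabeledSample
from .features import FeatureVector, REGIONS
from .geometry import GeometryError, LandmarkSet51, LandmarkSet68

__all__ = [
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_landmarks_json",
    "write_landmarks_json",
    "dataset_to_frame",
    "write_features_csv",
    "read_features_csv",
    "write_arff",
    "arff_document",
]


def _wrap_points(points: np.ndarray, source_id: str):
    if len(points) == 68:
        return LandmarkSet68(points, source_id=source_id)
    if len(points) == 51:
        return LandmarkSet51(points, source_id=source_id)
    raise GeometryError(f"expected 68 or 51 landmarks, got {len(points)}")


def read_landmarks_csv(path):
    """Read one landmark set from a CSV with columns index,x,y."""
    df = pd.read_csv(path)
    required = {"index", "x", "y"}
    if not required <= set(df.columns):
        raise GeometryError(f"landmark CSV needs columns {sorted(required)}, got {list(df.columns)}")
    df = df.sort_values("index")
    if not np.array_equal(df["index"].to_numpy(), np.arange(len(df))):
        raise GeometryError("landmark CSV indices must be 0..n-1 without gaps")
    return _wrap_points(df[["x", "y"]].to_numpy(float), Path(path).stem)


def write_landmarks_csv(lm, path) -> None:
    pts = lm.points
    df = pd.DataFrame({"index": np.arange(len(pts)), "x": pts[:, 0], "y": pts[:, 1]})
    df.to_csv(path, index=False)


def read_landmarks_json(path):
    """Read one landmark set from a JSON list of [x, y] pairs."""
    with open(path) as fh:
        data = json.load(fh)
    return _wrap_points(np.asarray(data, dtype=float), Path(path).stem)


def write_landmarks_json(lm, path) -> None:
    with open(path, "w") as fh:
        json.dump(lm.points.tolist(), fh)


# --------------------------------------------------------------------------
# Feature matrices
# --------------------------------------------------------------------------

def dataset_to_frame(ds: LabeledDataset) -> pd.DataFrame:
    """Feature matrix with source_id, subject_id and label columns."""
    df = pd.DataFrame(ds.X, columns=list(ds.feature_names))
    df.insert(0, "source_id", [s.features.source_id for s in ds.samples])
    df.insert(1, "subject_id", [s.subject_id for s in ds.samples])
    df["label"] = [s.label for s in ds.samples]
    return df


def write_features_csv(ds: LabeledDataset, path) -> None:
    dataset_to_frame(ds).to_csv(path, index=False)


def read_features_csv(path, *, region_tag: str | None = None, task: str = "detect") -> LabeledDataset:
    """Rebuild a LabeledDataset from a feature CSV written by this module."""
    df = pd.read_csv(path, dtype={"label": str})
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    if region_tag is None:
        for name, spec in REGIONS.items():
            if list(spec.feature_names) == feat_cols:
                region_tag = name
                break
        else:
            raise EvaluationError(f"feature columns {feat_cols} match no known region")
    samples = []
    for _, row in df.iterrows():
        fv = FeatureVector(
            row[feat_cols].to_numpy(float),
            region_tag=region_tag,
            source_id=str(row.get("source_id", "")),
        )
        samples.append(
            LabeledSample(
                features=fv,
                label=str(row["label"]),
                subject_id=str(row.get("subject_id", row.get("source_id", ""))),
            )
        )
    return LabeledDataset(tuple(samples), region_tag=region_tag, task=task)


# --------------------------------------------------------------------------
# ARFF
# --------------------------------------------------------------------------

def arff_document(ds: LabeledDataset, relation: str) -> str:
    """Serialize a dataset as a dense ARFF document.

    Numeric attributes in canonical f-order, the nominal class attribute
    last, values printed with full float precision.
    """
    if len(ds) == 0:
        raise EvaluationError("cannot serialize an empty dataset")
    dims = {len(s.features) for s in ds.samples}
    if len(dims) != 1:
        raise EvaluationError("mixed feature dimensionality")
    lines = [f"@relation {relation}", ""]
    for name in ds.feature_names:
        lines.append(f"@attribute {name} numeric")
    classes = ",".join(ds.label_set)
    lines.append(f"@attribute class {{{classes}}}")
    lines.extend(["", "@data"])
    for s in ds.samples:
        row = ",".join(repr(float(v)) for v in s.features.values)
        lines.append(f"{row},{s.label}")
    return "\n".join(lines) + "\n"


def write_arff(ds: LabeledDataset, relation: str, path) -> None:
    Path(path).write_text(arff_document(ds, relation))
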