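"""Optional image-based landmark acquisition.

The core package never requires a computer-vision backend; anything able to
take an image array and return 68 landmark points can be plugged in through
the :class:`LandmarkBackend` protocol (e.g. a dlib HOG detector + a
palsy-aware shape predictor).
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np

from .geometry import AcquisitionScale, GeometryError, LandmarkSet68

__all__ = ["LandmarkBackend", "DetectionFailure", "BackendUnavailable", "acquire_landmarks"]


class DetectionFailure(RuntimeError):
    """No face could be located in the image."""


class BackendUnavailable(RuntimeError):
    """No landmark-acquisition backend is installed/configured."""


@runtime_checkable
class LandmarkBackend(Protocol):
    def detect(self, image: np.ndarray) -> tuple[int, int, int, int] | None:
        """Face rectangle (x, y, w, h) on a grayscale image, or None."""
        ...

    def predict(self, image: np.ndarray, rect: tuple[int, int, int, int]) -> np.ndarray:
        """(68, 2) landmark coordinates for the face in ``rect``."""
        ...


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return img.astype(float)


def acquire_landmarks(
    image: np.ndarray,
    backend: LandmarkBackend | None,
    *,
    resize: bool = False,
    nW: int = 200,
    source_id: str = "",
) -> LandmarkSet68:
    """Gray conversion, (optional) resize for detection, prediction.

    With ``resize`` on, detection runs at width ``nW`` and the detected
    rectangle is re-scaled by sf = W/nW before landmark prediction, so the
    returned points live in original-image coordinates.
    """
    if backend is None:
        raise BackendUnavailable(
            "no landmark backend configured; install a face detector + shape "
            "predictor (e.g. dlib) and wrap it in a LandmarkBackend"
        )
    gray = _to_gray(image)
    h, w = gray.shape
    if resize:
        scale = AcquisitionScale.for_image(w, h, nW=nW)
        step = max(1, int(round(scale.sf)))
        small = gray[::step, ::step]
        rect = backend.detect(small)
        if rect is not None:
            rect = tuple(int(round(v * step)) for v in rect)
    else:
        rect = backend.detect(gray)
    if rect is None:
        raise DetectionFailure("no face found in image")
    pts = np.asarray(backend.predict(gray, rect), dtype=float)
    if pts.shape != (68, 2):
        raise GeometryError(f"backend returned shape {pts.shape}, expected (68, 2)")
    return LandmarkSet68(pts, source_id=source_id)
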