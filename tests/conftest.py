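import numpy as np
import pytest

from facesym.geometry import LandmarkSet51, LandmarkSet68
from facesym.synthetic import make_template


@pytest.fixture
def template():
    return make_template()


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture
def face_factory(rng):
    """Random plausible 51-point faces: template + bounded per-point jitter.

    Jitter is kept small enough that no feature denominator degenerates.
    """

    def make(n=1, jitter=4.0, seed=None):
        local_rng = rng if seed is None else np.random.default_rng(seed)
        base = make_template().landmarks.points
        faces = []
        for i in range(n):
            pts = base + local_rng.uniform(-jitter, jitter, size=base.shape)
            faces.append(LandmarkSet51(pts, source_id=f"rand{i}", tilt_corrected=True))
        return faces

    return make


@pytest.fixture
def random_68(rng):
    return LandmarkSet68(rng.uniform(0, 400, size=(68, 2)), source_id="raw68")
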