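import numpy as np
import pytest

from craniogen.synthetic import template_landmark_set


@pytest.fixture(scope="session")
def template():
    """The calibrated landmark template as a LandmarkSet (md not included)."""
    return template_landmark_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation (det +1) via QR."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture()
def make_rotation():
    return random_rotation
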