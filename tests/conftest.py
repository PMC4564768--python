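import numpy as np
import pytest

from floramorph import FlowerParams, make_flower


@pytest.fixture(scope="session")
def default_flower():
    """One default synthetic corolla (mesh + ground truth), shared read-only."""
    return make_flower(FlowerParams())


@pytest.fixture(scope="session")
def upright_flower():
    """Actinomorphic (zero-tilt) flower for symmetry-sensitive checks."""
    return make_flower(FlowerParams(tilt_angle_deg=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator, k: int = 3) -> np.ndarray:
    """Haar-ish random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(k, k)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
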