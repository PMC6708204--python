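import numpy as np
import pytest

from gliopix import PhantomSpec, generate_tumor_phantom


@pytest.fixture(scope="session")
def tumor_phantom():
    """One deterministic high-contrast tumor phantom with its ground truth."""
    return generate_tumor_phantom(PhantomSpec(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_halves():
    """64x64 image of two flat vertical halves (0 | 100) and the bright-half mask."""
    img = np.zeros((64, 64))
    img[:, 32:] = 100.0
    gt = np.zeros((64, 64), dtype=bool)
    gt[:, 32:] = True
    return img, gt
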