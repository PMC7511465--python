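import numpy as np
import pytest

from mvseg.volume import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_label(data, spacing=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(data, dtype=np.uint8), spacing, role="label")


def make_prob(data, spacing=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(data, dtype=np.float32), spacing, role="probability")


@pytest.fixture
def marker_volume():
    """8x6x5 intensity volume with a single bright voxel at (1, 2, 3)."""
    data = np.zeros((8, 6, 5), dtype=np.float32)
    data[1, 2, 3] = 99.0
    return Volume(data, (1.0, 1.0, 1.0), role="intensity")


def random_mask_pair(rng, shape=(16, 16, 16), density=None):
    """Two random binary masks with independent densities."""
    if density is None:
        density = rng.uniform(0.05, 0.6)
    a = (rng.random(shape) < density).astype(np.uint8)
    b = (rng.random(shape) < rng.uniform(0.05, 0.6)).astype(np.uint8)
    return make_label(a), make_label(b)
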