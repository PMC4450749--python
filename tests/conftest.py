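import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_pair(rng):
    """Two independent random 32x32 images on [0, 1]."""
    return rng.random((32, 32)), rng.random((32, 32))


def random_image(seed: int, shape=(16, 16)) -> np.ndarray:
    return np.random.default_rng(seed).random(shape)
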