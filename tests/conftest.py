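import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return rng.standard_normal((64, 64))


@pytest.fixture
def blobs():
    """Two well-separated Gaussian blobs, 50 + 50, labels in {-1, +1}."""
    g = np.random.default_rng(7)
    X = np.vstack([g.normal(0.0, 1.0, (50, 3)), g.normal(4.0, 1.0, (50, 3))])
    y = np.r_[-np.ones(50), np.ones(50)]
    return X, y
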