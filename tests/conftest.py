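import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric(n, rng, density=1.0, scale=1.0):
    """Random nonnegative symmetric weight matrix with zero diagonal."""
    w = rng.uniform(0.05, scale, size=(n, n))
    mask = rng.random((n, n)) < density
    w = np.triu(w * mask, k=1)
    w = w + w.T
    return w


@pytest.fixture
def small_design():
    from fcgraph.synthetic import generate_design

    return generate_design(3)
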