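import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_logistic(rng):
    """Small error-free logistic dataset (n=20, p=3) with known coefficients."""
    from boome import generate_true

    X, Y = generate_true(20, 3, [1.0, -0.5, 0.0], seed=11)
    return X, Y
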