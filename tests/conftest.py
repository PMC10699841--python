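import numpy as np
import pytest

from priorstack.data import GlmDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def gaussian_data(rng):
    """Small gaussian regression instance with a few real effects."""
    n, p = 60, 8
    X = rng.standard_normal((n, p))
    beta = np.array([1.0, -0.5, 0.8, 0.0, 0.0, 0.3, 0.0, 0.0])
    y = 0.4 + X @ beta + 0.5 * rng.standard_normal(n)
    return GlmDataset(X, y, "gaussian")


@pytest.fixture
def binomial_data(rng):
    n, p = 120, 5
    X = rng.standard_normal((n, p))
    beta = np.array([1.2, -0.8, 0.0, 0.5, 0.0])
    prob = 1.0 / (1.0 + np.exp(-(0.2 + X @ beta)))
    y = (rng.random(n) < prob).astype(float)
    return GlmDataset(X, y, "binomial")
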