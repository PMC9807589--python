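import numpy as np
import pytest

from canondx import MomentTable, TrainingSet, standardize


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def gaussian_training(rng):
    """One mildly correlated Gaussian class, standardized, I=5."""
    X = rng.standard_normal((300, 5)) + 0.6 * rng.standard_normal((300, 1))
    _, (std,) = standardize(TrainingSet("g", X))
    return std


@pytest.fixture
def gaussian_table(gaussian_training):
    return MomentTable(gaussian_training)
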