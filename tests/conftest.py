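import numpy as np
import pytest
from hypothesis import settings

from sparsemt.matrix import ActivityMatrix, FingerprintSet

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def small_regression():
    """4x3 regression matrix with one missing cell."""
    values = np.array([
        [10.0, 20.0, 30.0],
        [15.0, np.nan, 35.0],
        [-5.0, 0.0, 110.0],
        [50.0, 60.0, 70.0],
    ])
    observed = ~np.isnan(values)
    return ActivityMatrix(values, observed, ["c1", "c2", "c3", "c4"],
                          ["a1", "a2", "a3"], "regression")


@pytest.fixture
def small_classification():
    values = np.array([
        [1.0, 0.0],
        [0.0, 1.0],
        [1.0, 1.0],
        [0.0, np.nan],
    ])
    observed = ~np.isnan(values)
    return ActivityMatrix(values, observed, ["c1", "c2", "c3", "c4"],
                          ["a1", "a2"], "classification")


@pytest.fixture
def small_fps():
    rng = np.random.default_rng(0)
    bits = (rng.random((4, 16)) < 0.3).astype(np.uint8)
    bits[bits.sum(axis=1) == 0, 0] = 1
    return FingerprintSet(bits, ["c1", "c2", "c3", "c4"])


@pytest.fixture
def full_matrix_10x10():
    rng = np.random.default_rng(1)
    values = rng.normal(size=(10, 10)) * 10
    return ActivityMatrix(values, np.ones((10, 10), dtype=bool),
                          [f"c{i}" for i in range(10)],
                          [f"a{j}" for j in range(10)], "regression")
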