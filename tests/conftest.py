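import numpy as np
import pytest

from epistates.features import compute_feature_matrix, znormalize
from epistates.model import simulate_type_set


@pytest.fixture(scope="session")
def small_type_set():
    """30 simulated segments per brain-state type (fast shared dataset)."""
    return simulate_type_set(n_per_type=30, seed=101)


@pytest.fixture(scope="session")
def small_feature_matrix(small_type_set):
    return znormalize(compute_feature_matrix(small_type_set, dataset_id="model"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
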