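import numpy as np
import pytest

from vbmsvm import CohortConfig
import helpers


@pytest.fixture(scope="session")
def small_cohort():
    """A small separable cohort with preprocessing applied (session-scoped:
    generation plus the first solver JIT compile dominate)."""
    cfg = CohortConfig(n_case=12, n_control=12, grid_shape=(12, 12, 12), seed=7)
    return helpers.cohort_features(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
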