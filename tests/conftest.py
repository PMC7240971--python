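import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-panel cohort shared by read-only tests."""
    from metaboref import CohortConfig, simulate_cohort

    return simulate_cohort(CohortConfig(n_subjects=400, seed=7))
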