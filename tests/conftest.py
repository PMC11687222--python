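import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """The default 263-patient synthetic cohort, generated once per session."""
    from tigepk.synthetic_cohort import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(), seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
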