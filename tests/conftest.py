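import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fpcitbench as fb

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_geometry():
    """32-cube phantom layout — same invariants as the default, much faster."""
    return fb.default_geometry(size=32)


@pytest.fixture(scope="session")
def research_cohort():
    """Small high-separability cohort for classifier behaviour tests."""
    return fb.generate_cohort(fb.research_preset(seed=7, n_normal=60, n_abnormal=90))


@pytest.fixture(scope="session")
def clinical_cohort():
    return fb.generate_cohort(fb.clinical_preset(seed=7, n_normal=60, n_abnormal=90))


@pytest.fixture(scope="session")
def tiny_cohort():
    return fb.generate_cohort(fb.research_preset(seed=3, n_normal=12, n_abnormal=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
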