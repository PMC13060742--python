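import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from matppm.personalized_model import ModelSpec
from matppm.synthetic_data import homogeneous_cohort, study_fixture

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_bundle():
    """The 96 + 21 study-shaped synthetic dataset (expensive; shared)."""
    return study_fixture(seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A small homogeneous cohort for fast end-to-end exercises."""
    profiles, outcomes, truth = homogeneous_cohort(30, seed=11)
    return profiles, outcomes, truth


@pytest.fixture
def smat_spec():
    return ModelSpec(vision_variant="smat")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
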