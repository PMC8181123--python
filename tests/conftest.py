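import numpy as np
import pytest

from comvar.body import build_body_model, default_profile
from comvar.synth import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def model():
    return build_body_model(default_profile())


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small, fast cohort shared by I/O and pipeline tests."""
    return generate_cohort(SyntheticConfig(n_subjects=3, n_cycles=6, n_timepoints=100, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
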