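import numpy as np
import pytest

from morphotrait import CohortConfig, EffectSpec, generate_subjects
from morphotrait.covariates import nuisance_design


@pytest.fixture(scope="session")
def default_subjects():
    """Full-size cohort at the study's sample sizes (204 + 304)."""
    return generate_subjects(CohortConfig(seed=12345))


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_exploration=40, n_validation=60, seed=7)


@pytest.fixture(scope="session")
def small_subjects(small_config):
    return generate_subjects(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(99)


@pytest.fixture
def null_effects():
    return EffectSpec()


@pytest.fixture(scope="session")
def default_design(default_subjects):
    return nuisance_design(default_subjects)
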