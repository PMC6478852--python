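import numpy as np
import pytest

from gainloss.cohort import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject null-effect cohort shared by the slower integration tests."""
    return generate_cohort(CohortConfig(n_subjects=6, seed=77))


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size (31-subject) null-effect cohort at the default population."""
    return generate_cohort(CohortConfig(seed=2024))
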