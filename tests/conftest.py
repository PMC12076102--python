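import numpy as np
import pytest

from hdpsim import (CohortConfig, default_dgm, generate_base_cohort,
                    simulate_dataset)
from hdpsim._utils import child_seed


@pytest.fixture(scope="session")
def base_cohort():
    """Moderate-size synthetic base population shared across tests."""
    return generate_base_cohort(CohortConfig(n_base=4000, seed=3))


@pytest.fixture(scope="session")
def dgm(base_cohort):
    return default_dgm(base_cohort)


@pytest.fixture(scope="session")
def dataset(base_cohort, dgm):
    """One plasmode iteration (n=2500) for estimator-level tests."""
    return simulate_dataset(base_cohort, dgm, 2500, child_seed(3, 1, 0), 0)


@pytest.fixture(scope="session")
def randomized_cohort():
    """Base population with exposure independent of everything (both the
    covariate and latent exposure coefficient blocks forced to zero)."""
    return generate_base_cohort(CohortConfig(
        n_base=4000, seed=5, exposure_latent_coef=0.0, exposure_cov_scale=0.0))


def spec_dummies(X_spec):
    from hdpsim.orchestrate import _spec_dummies
    return _spec_dummies(X_spec)


@pytest.fixture(scope="session")
def investigator_design(dataset):
    from hdpsim.orchestrate import _investigator_matrix
    return _investigator_matrix(dataset)
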