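import numpy as np
import pytest
from dataclasses import replace

from pktd import StudyDesign, load_preset
from pktd.cohort import generate_pk_cohort, generate_td_cohort


@pytest.fixture(scope="session")
def pop():
    """Reference population model (final study estimates)."""
    return load_preset("reference")


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def pop_noiseless(pop):
    """No inter-individual variability, no residual error."""
    return replace(pop, omega={}, sigma_pk_prop=0.0, sigma_acute_prop=0.0,
                   sigma_chronic_add=0.0)


@pytest.fixture(scope="session")
def pk_cohort(pop, design):
    return generate_pk_cohort(pop, design, seed=1)


@pytest.fixture(scope="session")
def pk_cohort_noiseless(pop_noiseless, design):
    return generate_pk_cohort(pop_noiseless, design, seed=1)


@pytest.fixture(scope="session")
def td_cohort(pop, design):
    """TD cohort with the generating assumptions of the recovery experiments."""
    return generate_td_cohort(pop, design, seed=101, pk_iiv_in_td=False)


@pytest.fixture(scope="session")
def td_cohort_noiseless(pop_noiseless, design):
    return generate_td_cohort(pop_noiseless, design, seed=101,
                              pk_iiv_in_td=False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200203)
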