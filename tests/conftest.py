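import numpy as np
import pytest

from copkpd.params import CovariateRecord, table3_parameters
from copkpd.model import individual_from_population
from copkpd.synth import TrialDesign, default_designs, generate_trial


@pytest.fixture(scope="session")
def pop():
    return table3_parameters()


@pytest.fixture(scope="session")
def ref_cov(pop):
    """Reference subject: median age, Study 1."""
    return CovariateRecord(subject_id=1, age=pop.age_ref, study=1, weight=70.0)


@pytest.fixture(scope="session")
def typical_ind(pop, ref_cov):
    return individual_from_population(pop, ref_cov)


@pytest.fixture(scope="session")
def trial22(pop):
    """The standard virtual trial: 22 subjects split over the two arms."""
    return generate_trial(default_designs(22), pop, seed=42)


@pytest.fixture(scope="session")
def trial_small(pop):
    """A fast six-subject trial for unit-level estimation checks."""
    designs = [TrialDesign(n_subjects=3, study=1, surgery_duration=(120.0, 180.0)),
               TrialDesign(n_subjects=3, study=2, surgery_duration=(120.0, 180.0))]
    return generate_trial(designs, pop, seed=7)
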