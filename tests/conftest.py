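import numpy as np
import pytest

from lungsms.normative import NormativeDensityModel
from lungsms.synthetic import (
    CohortSpec,
    DiseaseSpec,
    generate_normative_cohort,
    generate_patient_cohort,
    generate_phantom,
    phantom_for_subject,
)


@pytest.fixture(scope="session")
def normative_cohort():
    """A default healthy cohort (n = 76) with known generating parameters."""
    return generate_normative_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def fitted_model(normative_cohort):
    return NormativeDensityModel(normative_cohort, log_base="10").fit()


@pytest.fixture(scope="session")
def truth_model():
    """The exact generating parameters packaged as a results object."""
    return CohortSpec(seed=7).truth_model()


@pytest.fixture(scope="session")
def patient_cohort():
    spec = CohortSpec(seed=3, n_subjects=180, male_fraction=98 / 180,
                      disease=DiseaseSpec())
    return generate_patient_cohort(spec)


@pytest.fixture(scope="session")
def normal_phantom(truth_model):
    """Phantom of a healthy male at exactly the normative-mean density."""
    spec = phantom_for_subject(truth_model, "male", 1.76, seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
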