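import numpy as np
import pytest

from tacropk import CohortDesign, PopulationParameters, generate_cohort


@pytest.fixture(scope="session")
def pop():
    """Published final-model parameters (the generator's ground truth)."""
    return PopulationParameters()


@pytest.fixture(scope="session")
def small_cohort(pop):
    """A small titrated cohort for fast estimation tests."""
    design = CohortDesign(n_subjects=20, n_days=8, seed=7)
    return generate_cohort(design, pop, np.random.default_rng(7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
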