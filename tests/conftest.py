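import numpy as np
import pytest

from voripk.params import IndividualParameters, published_model
from voripk.simulate import GeneratorConfig, generate_dataset

#: reference covariate vector of the published clearance model
REF_COVS = {"QCRP": 73.6, "CLCR": 71.8, "CRRT": 0.0, "PLT": 144.0, "PT": 15.0}


@pytest.fixture(scope="session")
def published():
    return published_model()


@pytest.fixture(scope="session")
def typical_individual():
    """Individual at the published typical values (reference covariates)."""
    return IndividualParameters(cl=3.55, vc=33.5, vp=138.0, q=52.8,
                                ka=1.2, f=0.835)


@pytest.fixture(scope="session")
def small_dataset():
    """60-subject synthetic dataset under the published model (seed 11)."""
    return generate_dataset(GeneratorConfig(n_subjects=60, seed=11))


@pytest.fixture(scope="session")
def medium_dataset():
    """150-subject synthetic dataset under the published model (seed 5)."""
    return generate_dataset(GeneratorConfig(n_subjects=150, seed=5))
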