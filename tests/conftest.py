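import numpy as np
import pytest

import nerdsim as ns
from nerdsim.inference import FitSpec


@pytest.fixture(scope="session")
def priors():
    return ns.default_priors()


@pytest.fixture(scope="session")
def mid_params(priors):
    """All coefficients at their prior means."""
    return priors.mean_parameters()


@pytest.fixture(scope="session")
def cfg():
    return ns.ModelConfig()


@pytest.fixture(scope="session")
def obs_model():
    return ns.ObservationModel()


@pytest.fixture(scope="session")
def patient(priors):
    """One moderate-injury synthetic patient on the weekly+monthly schedule."""
    return ns.synthesize_patient(seed=7, priors=priors)


@pytest.fixture(scope="session")
def quick_spec():
    return FitSpec(chains=3, iterations=1200, seed=123)


@pytest.fixture(scope="session")
def fitted_sample(patient, priors, quick_spec):
    return ns.fit_mcmc(patient, priors, quick_spec)


@pytest.fixture(scope="session")
def cohort(priors):
    """Medium synthetic cohort shared by risk/phenotype/validation tests."""
    return ns.generate_cohort(1500, priors=priors, seed=42, n_pilot=2500)


def random_parameters(rng):
    vals = rng.uniform(0.05, 0.95, size=12)
    return ns.NerdParameters(*vals, G0=rng.uniform(0.5, 1.5))
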