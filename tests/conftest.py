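import warnings

import numpy as np
import pytest

from flypop import datasets
from flypop.ipm import FitConfig, fit_ipm
from flypop.simulate import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def vaasa_census():
    return datasets.load_census("vaasa")


@pytest.fixture(scope="session")
def luoto_census():
    return datasets.load_census("luoto")


@pytest.fixture(scope="session")
def vaasa_productivity():
    return datasets.load_productivity("vaasa")


@pytest.fixture(scope="session")
def luoto_productivity():
    return datasets.load_productivity("luoto")


@pytest.fixture(scope="session")
def sim_default():
    """One default-world realization shared across read-only tests."""
    return simulate_population(SimulationConfig(seed=1234))


@pytest.fixture(scope="session")
def small_fit(sim_default):
    """A reduced-length IPM fit on the shared simulated dataset."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_ipm(
            sim_default.census, sim_default.captures,
            sim_default.productivity,
            FitConfig(chains=2, iterations=2000, burnin=800, thin=3, seed=9))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
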