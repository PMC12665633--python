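import warnings

import numpy as np
import pytest

from mesotox.simulate import SimConfig, simulate_experiment


def pytest_configure(config):
    # arviz emits a refactor FutureWarning on import; irrelevant here
    warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic experiment at the default study conditions."""
    return simulate_experiment(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def conc(default_dataset):
    return default_dataset.conc_for_tank()


@pytest.fixture(scope="session")
def light_mcmc():
    """Reduced sampler settings for unit tests."""
    return dict(chains=2, warmup=300, draws=500, thin=4)


@pytest.fixture(scope="session")
def week6_posterior(default_dataset, conc, light_mcmc):
    """A fitted week-6 hormetic model shared across tests."""
    from mesotox.hormesis import (HormesisModelSpec, fit_hormetic_model,
                                  observations_from_table)
    obs = observations_from_table(default_dataset.amphipods, conc, week=6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_hormetic_model(obs, HormesisModelSpec(seed=42, **light_mcmc),
                                  check_convergence=False)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
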