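import numpy as np
import pytest
from hypothesis import settings

from toxber import (
    McmcConfig,
    SyntheticConfig,
    fit_error_model,
    generate_portfolio,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    """The default synthetic study conditions (30 scenarios, paper-shaped)."""
    return SyntheticConfig(seed=3)


@pytest.fixture(scope="session")
def portfolio(default_config):
    return generate_portfolio(default_config)


@pytest.fixture(scope="session")
def main_fit(portfolio):
    """One well-mixed fit of the default portfolio, shared across tests."""
    ds, _ = portfolio
    return fit_error_model(ds, mcmc=McmcConfig(chains=4, warmup=800, samples=800, seed=7))


@pytest.fixture(scope="session")
def small_mcmc():
    """Short chains for tests that need many refits."""
    return McmcConfig(chains=2, warmup=300, samples=300, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
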