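import pytest

from econeval import PSAConfig, load_cost_ledger, load_default_config, sample_draws
from econeval.config_io import default_ledger_path


@pytest.fixture(scope="session")
def default_config():
    return load_default_config()


@pytest.fixture(scope="session")
def fixture_specs(default_config):
    return default_config.outcomes


@pytest.fixture(scope="session")
def fixture_ledger():
    return load_cost_ledger(default_ledger_path())


@pytest.fixture(scope="session")
def normal_draws(fixture_specs):
    """10,000 base-case (normal-family) simulations at a fixed seed."""
    return sample_draws(fixture_specs, PSAConfig(n_sims=10_000, seed=947251))
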