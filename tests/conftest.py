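import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from avitherm import synthetic as syn

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> syn.GeneratorConfig:
    return syn.GeneratorConfig(seed=12345)


@pytest.fixture(scope="session")
def population(default_config):
    return syn.generate_population(default_config)


@pytest.fixture(scope="session")
def profiles(default_config, population):
    return syn.generate_profiles(population, default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
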