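import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from fibresim import (
    SimConfig,
    SyntheticPopulationConfig,
    generate_initial_population,
    run_attrition,
)


@pytest.fixture(scope="session")
def default_population():
    """Synthetic pre-hydrolysis population under generator defaults (10k fibres)."""
    return generate_initial_population(SyntheticPopulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_trajectory(default_population):
    """One full mechanical attrition run under all defaults."""
    return run_attrition(default_population.lengths, config=SimConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
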