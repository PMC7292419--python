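import numpy as np
import pytest

from cwlearn import TaskConfig, run_behavioral_battery, simulate_cohort


@pytest.fixture(scope="session")
def default_config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """The full study-scale simulation: 24 subjects x 4 sessions x 380 trials."""
    return simulate_cohort(default_config, master_seed=0)


@pytest.fixture(scope="session")
def behavioral_table(default_config, default_cohort):
    return run_behavioral_battery(default_config, cohort=default_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
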