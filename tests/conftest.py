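import numpy as np
import pytest

from vtamua import SimConfig, build_trial_count_fixture


@pytest.fixture(scope="session")
def fixture_trials():
    return build_trial_count_fixture()


@pytest.fixture
def small_config():
    return SimConfig(n_pigeons=1, sessions_per_pigeon=3, trials_per_session=20, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
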