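import numpy as np
import pytest

from ankleuq import LoadSchedule, default_ankle_fixture, sweep_loads


@pytest.fixture(scope="session")
def fixture_model():
    return default_ankle_fixture()


@pytest.fixture(scope="session")
def default_sweep(fixture_model):
    return sweep_loads(fixture_model, LoadSchedule.default())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
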