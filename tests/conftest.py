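import numpy as np
import pytest

from oehr import SimulationScenario, generate_dataset, select_smoothing_by_aic


@pytest.fixture(scope="session")
def symmetric_scenario():
    return SimulationScenario(-2.0, 2.0, 0.0, n=500, reps=100, seed=11)


@pytest.fixture(scope="session")
def symmetric_data(symmetric_scenario):
    return generate_dataset(symmetric_scenario, 0)


@pytest.fixture(scope="session")
def symmetric_fit(symmetric_data):
    return select_smoothing_by_aic(symmetric_data)


@pytest.fixture(scope="session")
def severe_data():
    sc = SimulationScenario(-4.0 / 3.0, 4.0, 1.0, n=500, reps=1, seed=5)
    return generate_dataset(sc, 0)


@pytest.fixture(scope="session")
def severe_fit(severe_data):
    return select_smoothing_by_aic(severe_data)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
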