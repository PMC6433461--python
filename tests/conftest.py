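import numpy as np
import pytest

from parbkin import KineticModel, SimulationTruth, SwitchingSchedule


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def model():
    # reference rates: kon 4e5 M^-1 s^-1, koff 0.1 s^-1
    return KineticModel(kon=4e5, koff=0.1)


@pytest.fixture
def truth(model):
    return SimulationTruth(model=model, n_sites=200, k_bleach=0.0, seed=11)


@pytest.fixture
def square_schedule():
    return SwitchingSchedule.square_wave(250e-9, period=60.0, exchange_time=6.5)
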