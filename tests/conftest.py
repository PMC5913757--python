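import numpy as np
import pytest

import rtnet as rt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gamma_10_10():
    """Ten-step chain law with unit mean: gamma(shape=10, rate=10)."""
    return rt.GammaRT(10.0, 10.0)


@pytest.fixture
def single_transition_network(gamma_10_10):
    """Minimal communication network: S0 -> Sa with a gamma(10,10) law."""
    return rt.CommunicationNetwork(
        states=[rt.CellState("S0"), rt.CellState("Sa", is_absorbing=True)],
        transitions=[rt.TransitionSpec("S0", "Sa", law=gamma_10_10)],
        initial={"S0": 1.0},
    )
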