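import numpy as np
import pytest

from ordflux import ExchangeState, RateConstants, SimulationConfig


@pytest.fixture
def default_config():
    """Standard non-exchange condition: 0.2 uM protein, 5 uM PS in
    membrane A, 100 uM membranes."""
    return SimulationConfig()


@pytest.fixture
def symmetric_config():
    """PS split equally between identical membranes."""
    state = ExchangeState(o_free=0.2, ps_a=2.5, ps_b=2.5, m_a=100.0, m_b=100.0)
    return SimulationConfig(initial_state=state)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
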