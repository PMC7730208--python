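import numpy as np
import pytest

from nirsbci import SimConfig, simulate_recording


@pytest.fixture(scope="session")
def sim_session():
    """Default seeded synthetic session: (hbo, hbr, truth)."""
    return simulate_recording(SimConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
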