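import numpy as np
import pytest

import ripplephys as rp


@pytest.fixture(scope="session")
def small_session() -> rp.Session:
    """120 s, 8-channel session with theta, ripples and no stimulation."""
    return rp.generate_session(rp.SimConfig(duration_s=120, seed=1))


@pytest.fixture(scope="session")
def table1():
    return rp.make_table1_fixture()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
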