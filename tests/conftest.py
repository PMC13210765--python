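import numpy as np
import pytest

from pulseloop.realtime import THETA, SMR, filter_for_band


@pytest.fixture(scope="session")
def theta_filter():
    return filter_for_band(THETA, rate=1000.0)


@pytest.fixture(scope="session")
def smr_filter():
    return filter_for_band(SMR, rate=1000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)
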