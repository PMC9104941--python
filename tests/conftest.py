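import numpy as np
import pytest

from radarvitals import forward_model


@pytest.fixture
def chirp():
    return forward_model.ChirpConfig()


@pytest.fixture
def default_scenario():
    return forward_model.DisplacementScenario()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
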