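import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_plan():
    from ssdgp.netbuilder import default_plan

    return default_plan("ssd-pd", 96, 0.125)
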