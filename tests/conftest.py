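import numpy as np
import pytest

from stancesim import musculotendon as mt


@pytest.fixture(scope="session")
def mtus():
    return mt.load_mtu_params()


@pytest.fixture(scope="session")
def so(mtus):
    return mtus["SO"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
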