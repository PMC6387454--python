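import numpy as np
import pytest

from uspiorelax.sequences import PROTOCOL_PRESETS, hifi_protocol, irse_series


@pytest.fixture(scope="session")
def protocol():
    """The five DESPOT1-HIFI acquisitions (3 sGRE + 2 IR-sGRE)."""
    return hifi_protocol()


@pytest.fixture(scope="session")
def irse_seqs():
    return irse_series()


@pytest.fixture(scope="session")
def me_seq():
    return PROTOCOL_PRESETS["me_sgre"]


@pytest.fixture
def rng():
    return np.random.default_rng(20190212)
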