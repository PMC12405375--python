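import numpy as np
import pytest

from lift import synthetic_data as sd


@pytest.fixture(scope="session")
def default_map():
    """Desk-scale 17-LG apple-like map (1,700 SNPs, 1,360 cM)."""
    return sd.make_apple_map(seed=7)


@pytest.fixture(scope="session")
def mr5_founders(default_map):
    """75%-exotic donor with its R-gene on LG03, plus domestic pool."""
    return sd.make_founders(default_map, sd.mr5_like_spec(), seed=3)


@pytest.fixture(scope="session")
def evereste_founders(default_map):
    """50%-exotic donor with its R-gene on LG12."""
    return sd.make_founders(default_map, sd.evereste_like_spec(), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
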