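import numpy as np
import pytest

from laughpd import FramingConfig, build_filterbank


@pytest.fixture(scope="session")
def mel_bank():
    return build_filterbank("mel")


@pytest.fixture(scope="session")
def framing():
    return FramingConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
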