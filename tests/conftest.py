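import numpy as np
import pytest

from nrf2net.fccs_quant import ConfocalVolume


@pytest.fixture(scope="session")
def volume() -> ConfocalVolume:
    """LSM-style confocal volume used throughout: 0.35 fL, s = 5, w0 = 0.2 um."""
    return ConfocalVolume(v_eff_fL=0.35, s=5.0, w0_um=0.2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
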