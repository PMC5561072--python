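import numpy as np
import pytest

from polydfs import BondParams, WLCParams, thermal_energy


@pytest.fixture(scope="session")
def kBT() -> float:
    return thermal_energy()


@pytest.fixture()
def wlc() -> WLCParams:
    return WLCParams(l_app=0.4, L=150.0)


@pytest.fixture()
def bond() -> BondParams:
    return BondParams(k_off=0.5, x_t=0.3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
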