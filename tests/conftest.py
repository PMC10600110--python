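import numpy as np
import pytest

from n2ofix.gases import GasSpec
from n2ofix.simulate import SimulationConfig


@pytest.fixture(scope="session")
def gases():
    return {name: GasSpec.from_constants(name) for name in ("N2", "Ar", "O2", "N2O")}


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20231025)
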