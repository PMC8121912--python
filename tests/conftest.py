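import numpy as np
import pytest

from synapsim.geometry import SynapseGeometry
from synapsim.params import KineticParams


@pytest.fixture(scope="session")
def geometry():
    return SynapseGeometry()


@pytest.fixture(scope="session")
def params():
    return KineticParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
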