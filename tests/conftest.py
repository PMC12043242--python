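import numpy as np
import pytest

from cyclopep.fixtures import closed_backbone
from cyclopep.geometry import TorsionConformation, forward_kinematics


@pytest.fixture(scope="session")
def closed7():
    """An exactly closed 7-residue conformation (session-cached)."""
    return closed_backbone(7, seed=1)


@pytest.fixture(scope="session")
def closed7_struct(closed7):
    return forward_kinematics(closed7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_conformation(n, rng):
    return TorsionConformation(rng.uniform(-180, 180, n),
                               rng.uniform(-180, 180, n))
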