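import numpy as np
import pytest

from livertrack.grid import GridSpec
from livertrack.phantom import (MotionParams, PhantomConfig,
                                make_breathing_phases, make_phantom)


@pytest.fixture(scope="session")
def phantom():
    """Desk-scale phantom: 162-node liver mesh on a 32^3 grid."""
    return make_phantom(PhantomConfig(grid=GridSpec.centered(32, 8.0)), seed=7)


@pytest.fixture(scope="session")
def phases(phantom):
    return make_breathing_phases(phantom, 10, MotionParams(), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
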