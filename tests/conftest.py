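import numpy as np
import pytest

from tpmsbone.geometry import DesignSpec, voxelize_shell
from tpmsbone.simulate import initial_state


@pytest.fixture(scope="session")
def s_rve_small():
    """S-type RVE at a coarse resolution usable for FE tests."""
    return voxelize_shell(DesignSpec(kind="S", resolution=16))


@pytest.fixture(scope="session")
def s_state_small(s_rve_small):
    return initial_state(s_rve_small)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
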