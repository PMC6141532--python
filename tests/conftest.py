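import numpy as np
import pytest

from devoxel import DevoConfig, GridSpec, PhysicsConfig

# Toy study conditions used wherever a full-scale simulation would be
# wasteful: a 3x3x2 body living 5 actuation cycles (1.25 s) under softer,
# coarser physics constants. Chosen once; documented in docs/methods.md.
TOY_RECORD = 0.03


@pytest.fixture
def toy_grid():
    return GridSpec(3, 3, 2)


@pytest.fixture
def toy_devo():
    return DevoConfig(n_cycles=5)


@pytest.fixture
def toy_phys():
    return PhysicsConfig.toy()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
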