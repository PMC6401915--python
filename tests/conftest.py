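import numpy as np
import pytest

import cdshape as cs


@pytest.fixture(scope="session")
def regular_cd():
    """The undistorted reference heptamer: (Conformation, CDTopology)."""
    return cs.build_regular_cd()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def substituted_cd():
    """Reference heptamer with one exterior and one inserted HP group."""
    conf, topo = cs.build_regular_cd()
    conf, topo = cs.place_hp(conf, topo, 1, "O6", "exterior", 8.0)
    conf, topo = cs.place_hp(conf, topo, 4, "O2", "inserted", 1.5)
    return conf, topo
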