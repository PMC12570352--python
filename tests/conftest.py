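import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cube():
    from ridsim.systems import cube_mesh

    return cube_mesh(edge=2.0)


@pytest.fixture(scope="session")
def icosphere():
    from ridsim.systems import icosphere_mesh

    return icosphere_mesh(subdivisions=2, radius=10.0)
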