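import numpy as np
import pytest

from nanoadhere.mesh import MembraneParams, build_flat_patch
from nanoadhere import fixtures as fx


@pytest.fixture
def flat_patch():
    return build_flat_patch(160.0, 10.0)


@pytest.fixture
def flat_params():
    return MembraneParams(kappa=20.0, sigma=0.0, L=160.0)


@pytest.fixture(scope="session")
def icosphere100():
    return fx.icosphere(radius=100.0, subdivisions=3)


@pytest.fixture(scope="session")
def cylinder50():
    return fx.closed_cylinder(radius=50.0, height=400.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
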