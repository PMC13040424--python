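import numpy as np
import pytest

from cervimetry.phantom_gen import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def straight_phantom():
    """Default straight tube: L=32 mm, canal r=2 mm, 0.8 mm voxels."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def quarter_torus_phantom():
    """Quarter-circle canal, centerline radius 20 mm (arc pi*R/2)."""
    spec = PhantomSpec(canal_length=np.pi * 20.0 / 2.0, curvature_radius=20.0)
    return make_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
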