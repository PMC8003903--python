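import numpy as np
import pytest

from chondroquant.phantom import PhantomSpec, make_condyle_models


@pytest.fixture(scope="session")
def coarse_spec():
    """Small, fast phantom used across tests."""
    return PhantomSpec(noise_sigma=0.0, mesh_resolution=3.0, spacing=(1.5, 1.5, 3.0), margin=1.5)


@pytest.fixture(scope="session")
def coarse_models(coarse_spec):
    return make_condyle_models(coarse_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def icosphere_mesh(radius: float, subdivisions: int = 2, center=(0.0, 0.0, 0.0)):
    from chondroquant.meshmodel import SurfaceMesh
    from chondroquant.phantom import icosphere

    unit = icosphere(subdivisions)
    return SurfaceMesh(unit.vertices * radius + np.asarray(center), unit.faces)
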