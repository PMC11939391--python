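import numpy as np
import pytest

from imasim import anatomy, metrics
from imasim.mesh_core import PolylineMesh, TriangleMesh


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def fascia_scene():
    """Small pinned fascia sheet with its constraint set and particle system."""
    spec = anatomy.FasciaSpec(width=0.08, height=0.12, resolution=(7, 9),
                              total_mass=0.05)
    return anatomy.build_fascia(spec)


@pytest.fixture()
def parallel_squares():
    """Two parallel unit squares 1 m apart (strand-generation playground)."""
    def square(z):
        return TriangleMesh(
            np.array([[0, 0, z], [1, 0, z], [1, 1, z], [0, 1, z]], dtype=float),
            np.array([[0, 1, 2], [0, 2, 3]]))
    return square(0.0), square(1.0)


@pytest.fixture()
def straight_centerline_config():
    """SAI config: straight centerline along +y, heart on the +x side."""
    cl = np.array([[0.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    return metrics.SAIConfig(
        centerline=PolylineMesh(cl, np.array([[0, 1]]), np.array([0.003, 0.003])),
        cardiac_side_vector=np.array([1.0, 0.0, 0.0]),
        projection_normal=np.array([0.0, 0.0, 1.0]))
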