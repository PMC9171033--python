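import numpy as np
import pytest
import trimesh

from osteomap import TriangleMesh, make_template_mandible
from osteomap.synthetic import TemplateParams


@pytest.fixture
def tetrahedron() -> TriangleMesh:
    v = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f, "tet")


@pytest.fixture
def sphere() -> TriangleMesh:
    m = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces), "sphere")


@pytest.fixture
def small_sphere() -> TriangleMesh:
    m = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
    return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces), "sphere")


@pytest.fixture(scope="session")
def small_template():
    return make_template_mandible(TemplateParams(n_vertices=220), seed=7)


@pytest.fixture(scope="session")
def study_template():
    """Default 653-vertex template used by the recovery checks."""
    return make_template_mandible(seed=11)


def random_rigid(rng, max_angle=0.5):
    """A random modest rigid motion (rotation magnitude <= max_angle rad)."""
    from scipy.spatial.transform import Rotation

    from osteomap import RigidTransform

    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(axis * rng.uniform(0, max_angle)).as_matrix()
    return RigidTransform(R, rng.uniform(-5, 5, 3))
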