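import math

import numpy as np
import pytest

import vesiturn as vt


@pytest.fixture
def corner_tetra():
    """Tetrahedron at the origin corner of the unit cube (volume 1/6)."""
    pos = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return vt.build_mesh(pos, faces)


@pytest.fixture
def cube_mesh():
    """Triangulated unit cube (8 vertices, 12 faces)."""
    import itertools

    from scipy.spatial import ConvexHull

    pos = np.array(list(itertools.product([0, 1], repeat=3)), float)
    hull = ConvexHull(pos)
    faces = hull.simplices.copy()
    c = pos.mean(axis=0)
    r = pos[faces]
    n = np.cross(r[:, 1] - r[:, 0], r[:, 2] - r[:, 0])
    flip = np.einsum("ij,ij->i", n, r.mean(axis=1) - c) < 0
    faces[flip] = faces[flip][:, ::-1]
    return vt.build_mesh(pos, faces)


@pytest.fixture
def icosa():
    return vt.icosahedron()


def perturbed_icosphere(subdivisions=2, amplitude=0.05, seed=0):
    """Icosphere rescaled to mean face area 1, with vertex jitter."""
    rng = np.random.default_rng(seed)
    m = vt.icosphere(subdivisions=subdivisions, radius=1.0)
    cache = vt.MeshCache(m)
    m.positions *= math.sqrt(m.n_faces / cache.total_area)
    m.positions += amplitude * rng.standard_normal(m.positions.shape)
    return m


@pytest.fixture
def bumpy_sphere():
    return perturbed_icosphere()


@pytest.fixture(scope="session")
def vesicle320():
    """Equilibrated 320-face vesicle shared across tests (do not mutate)."""
    return vt.generate_vesicle(320, seed=0)


@pytest.fixture(scope="session")
def vesicle1000():
    """Equilibrated 1000-face reference vesicle (do not mutate)."""
    return vt.generate_vesicle(1000, seed=0)
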