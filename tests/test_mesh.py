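"""Discrete geometry of closed triangle meshes."""

import math

import numpy as np
import pytest

import vesiturn as vt
from vesiturn.mesh import (
    DuplicateFaceError,
    MeshCache,
    NonManifoldError,
    OpenMeshError,
    OrientationError,
)
from tests.conftest import perturbed_icosphere


class TestBuildMesh:
    def test_tetrahedron_euler(self, corner_tetra):
        assert vt.euler_characteristic(corner_tetra) == 2

    def test_icosahedron_edge_count(self, icosa):
        cache = MeshCache(icosa)
        assert len(cache.edges) == 30  # E = 3F/2 with F = 20
        assert vt.euler_characteristic(icosa) == 2

    def test_inconsistent_orientation_rejected(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        # second face traverses edge (0,1) in the same direction as the first
        faces = np.array([[0, 1, 2], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
        with pytest.raises(OrientationError):
            vt.build_mesh(pos, faces)

    def test_nonmanifold_edge_rejected(self):
        pos = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0]], float
        )
        faces = np.array(
            [[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3], [0, 1, 4]]
        )
        with pytest.raises(NonManifoldError):
            vt.build_mesh(pos, faces)

    def test_duplicate_face_rejected(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [2, 1, 0]])
        with pytest.raises(DuplicateFaceError):
            vt.build_mesh(pos, faces)

    def test_orientation_normalized_outward(self, corner_tetra):
        # rebuilding from reversed faces restores positive volume
        m = vt.build_mesh(corner_tetra.positions, corner_tetra.faces[:, ::-1])
        assert vt.enclosed_volume(m) > 0


class TestEnclosedVolume:
    def test_corner_tetrahedron(self, corner_tetra):
        assert vt.enclosed_volume(corner_tetra) == pytest.approx(1.0 / 6.0)

    def test_unit_cube(self, cube_mesh):
        assert vt.enclosed_volume(cube_mesh) == pytest.approx(1.0)

    def test_icosphere_approaches_sphere_from_below(self):
        exact = 4.0 / 3.0 * math.pi * 2.0**3
        vols = [
            vt.enclosed_volume(vt.icosphere(subdivisions=n, radius=2.0))
            for n in (1, 2, 3)
        ]
        assert all(v < exact for v in vols)
        errs = [exact - v for v in vols]
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] / exact < 0.01

    def test_open_mesh_raises(self):
        patch = vt.planar_patch(3)
        with pytest.raises(OpenMeshError):
            vt.enclosed_volume(patch)

    def test_translation_invariant_and_odd_under_reflection(self, corner_tetra):
        shifted = vt.TriangleMesh(
            corner_tetra.positions + np.array([5.0, -2.0, 3.0]),
            corner_tetra.faces,
        )
        assert vt.enclosed_volume(shifted) == pytest.approx(1.0 / 6.0)
        reversed_mesh = vt.TriangleMesh(
            corner_tetra.positions, corner_tetra.faces[:, ::-1].copy()
        )
        assert vt.enclosed_volume(reversed_mesh) == pytest.approx(-1.0 / 6.0)


class TestDihedralAngle:
    def test_cube_edges_convex_right_angle(self, cube_mesh):
        cache = MeshCache(cube_mesh)
        # cube dihedrals are either face diagonals (flat) or edges (+pi/2)
        thetas = np.round(cache.edge_theta, 12)
        assert set(np.unique(thetas)) == {0.0, round(math.pi / 2, 12)}

    def test_regular_tetrahedron_value(self):
        m = vt.tetrahedron()
        cache = MeshCache(m)
        edge = tuple(int(x) for x in cache.edges[0])
        expected = math.pi - math.acos(1.0 / 3.0)
        assert vt.edge_dihedral_angle(m, edge) == pytest.approx(expected)

    def test_coplanar_faces_zero(self):
        patch = vt.planar_patch(3)
        cache = MeshCache(patch, allow_boundary=True)
        interior = cache.edge_faces[:, 1] >= 0
        assert np.allclose(cache.edge_theta[interior], 0.0)

    def test_sign_flips_under_reflection(self, corner_tetra):
        edge = (0, 1)
        theta = vt.edge_dihedral_angle(corner_tetra, edge)
        # reflecting positions while keeping the winding reverses the
        # orientation, so the fold looks concave from the new normals
        raw = vt.TriangleMesh(
            corner_tetra.positions * np.array([1.0, 1.0, -1.0]),
            corner_tetra.faces.copy(),
        )
        assert vt.edge_dihedral_angle(raw, edge) == pytest.approx(-theta)
        # the true mirror surface (reflected and rewound) is still convex
        mirrored = vt.build_mesh(
            corner_tetra.positions * np.array([1.0, 1.0, -1.0]),
            corner_tetra.faces[:, ::-1],
        )
        assert vt.edge_dihedral_angle(mirrored, edge) == pytest.approx(theta)


class TestVertexCurvature:
    def test_flat_interior_vertex(self):
        patch = vt.planar_patch(3)
        m_i, a_i, deficit = vt.vertex_curvature_measures(patch, 4)
        assert m_i == pytest.approx(0.0, abs=1e-12)
        assert deficit == pytest.approx(0.0, abs=1e-12)
        assert a_i > 0

    def test_icosahedron_angle_deficit(self, icosa):
        _, _, deficit = vt.vertex_curvature_measures(icosa, 0)
        assert deficit == pytest.approx(2 * math.pi - 5 * math.pi / 3)

    def test_total_mean_curvature_converges_to_4piR(self):
        radius = 2.0
        errs = []
        for n in (1, 2, 3):
            cache = MeshCache(vt.icosphere(subdivisions=n, radius=radius))
            errs.append(abs(cache.vertex_M.sum() - 4 * math.pi * radius))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] / (4 * math.pi * radius) < 0.01

    def test_gauss_bonnet_total_deficit(self, bumpy_sphere):
        cache = MeshCache(bumpy_sphere)
        assert cache.angle_deficits().sum() == pytest.approx(
            4 * math.pi, abs=1e-9
        )

    def test_vertex_areas_partition_total_area(self, bumpy_sphere):
        cache = MeshCache(bumpy_sphere)
        assert cache.vertex_A.sum() == pytest.approx(
            cache.total_area, rel=1e-12
        )
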