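"""Remeshing moves: legality, bookkeeping and local trial energies."""

import math

import numpy as np
import pytest

import vesiturn as vt
from vesiturn.energetics import MechanicalParams
from vesiturn.mesh import MeshCache
from vesiturn import topology as topo
from tests.conftest import perturbed_icosphere


class TestFlip:
    def test_octahedron_flip_swaps_diagonal(self):
        # edge (+x,+y) has opposite vertices (+z,-z), which are unconnected
        m = vt.octahedron()
        v, e, f = m.n_vertices, len(MeshCache(m).edges), m.n_faces
        vt.flip_edge(m, (0, 2))
        cache = MeshCache(m)
        assert (m.n_vertices, len(cache.edges), m.n_faces) == (v, e, f)
        assert (4, 5) in cache.edge_index  # new diagonal +z,-z
        assert (0, 2) not in cache.edge_index

    def test_flip_is_involution_on_connectivity(self):
        m = vt.octahedron()
        before = set(MeshCache(m).edge_index)
        vt.flip_edge(m, (0, 2))
        vt.flip_edge(m, (4, 5))
        assert set(MeshCache(m).edge_index) == before
        assert vt.euler_characteristic(m) == 2

    def test_rejected_when_opposite_vertices_connected(self):
        # on a tetrahedron every vertex pair is already an edge
        m = vt.tetrahedron()
        before = m.faces.copy()
        with pytest.raises(topo.IllegalMove, match="already connected"):
            vt.flip_edge(m, (0, 1))
        np.testing.assert_array_equal(m.faces, before)


class TestSplit:
    def test_icosahedron_counts(self, icosa):
        m = icosa.copy()
        vol0 = vt.enclosed_volume(m)
        vt.split_pair(m, (0, 11))
        cache = MeshCache(m)
        assert (m.n_faces, m.n_vertices, len(cache.edges)) == (22, 13, 33)
        assert vt.euler_characteristic(m) == 2
        assert vt.enclosed_volume(m) == pytest.approx(vol0)

    def test_geometry_pointwise_unchanged(self, icosa):
        m = icosa.copy()
        area0 = MeshCache(m).total_area
        vt.split_pair(m, (0, 11))
        assert MeshCache(m).total_area == pytest.approx(area0)


class TestMerge:
    def test_icosahedron_counts(self, icosa):
        m = icosa.copy()
        vt.merge_pair(m, (0, 11))
        cache = MeshCache(m)
        assert (m.n_faces, m.n_vertices, len(cache.edges)) == (18, 11, 27)
        assert vt.euler_characteristic(m) == 2

    def test_link_condition_rejection(self):
        # flipping one octahedron edge connects the two poles, which then
        # share all four equatorial vertices -- more than the two apices
        m = vt.octahedron()
        vt.flip_edge(m, (0, 2))
        gate = topo.QualityGate(min_faces=4)
        before = (m.positions.copy(), m.faces.copy())
        with pytest.raises(topo.IllegalMove, match="link condition"):
            vt.merge_pair(m, (4, 5), gate=gate)
        np.testing.assert_array_equal(m.positions, before[0])
        np.testing.assert_array_equal(m.faces, before[1])

    def test_minimum_size_guard(self):
        m = vt.octahedron()
        edge = tuple(int(x) for x in MeshCache(m).edges[0])
        with pytest.raises(topo.IllegalMove, match="minimum size"):
            vt.merge_pair(m, edge)

    def test_split_then_merge_restores_counts(self, icosa):
        m = icosa.copy()
        new_vertex = 12  # appended by the split
        vt.split_pair(m, (0, 11))
        cache = MeshCache(m)
        # collapsing either stub of the split edge restores the counts
        vt.merge_pair(m, (new_vertex, 0))
        assert m.n_faces == 20
        assert m.n_vertices == 12
        assert vt.euler_characteristic(m) == 2


class TestTrialDelta:
    @pytest.mark.parametrize("kind", ["flip", "split", "merge"])
    def test_local_equals_global_recomputation(self, kind):
        rng = np.random.default_rng(11)
        mesh = perturbed_icosphere(subdivisions=2, amplitude=0.05, seed=1)
        params = MechanicalParams(
            K_c=3.0, v_eq=0.9 * vt.enclosed_volume(mesh), kappa_act=2.0
        )
        center = vt.active_center(mesh)
        cache = MeshCache(mesh)
        tested = 0
        while tested < 25:
            k = int(rng.integers(len(cache.edges)))
            edge = tuple(int(x) for x in cache.edges[k])
            try:
                d_local = vt.trial_delta(mesh, kind, edge, params, center=center)
            except topo.IllegalMove:
                continue
            m2 = mesh.copy()
            u0 = vt.total_energy(m2, params, center=center)
            getattr(vt, f"{kind}_edge" if kind == "flip" else f"{kind}_pair")(
                m2, edge
            )
            u1 = vt.total_energy(m2, params, center=center)
            assert d_local == pytest.approx(u1 - u0, abs=1e-9)
            tested += 1

    def test_split_on_compressed_sphere_raises_area_energy(self):
        mesh = vt.icosphere(subdivisions=2, radius=1.0)
        cache = MeshCache(mesh)
        mesh.positions *= math.sqrt(0.9 * mesh.n_faces / cache.total_area)
        params = MechanicalParams(K_v=0, K_c=0, K_r=0, kappa_act=0)
        cache = MeshCache(mesh)
        edge = tuple(int(x) for x in cache.edges[0])
        assert vt.trial_delta(mesh, "split", edge, params) > 0

    def test_symmetric_quad_flip_zero_area_delta(self):
        # square-based pyramid: flipping the base diagonal exchanges two
        # congruent right triangles for two others of the same total area
        pos = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0.5, 0.5, 1.0]],
            float,
        )
        faces = np.array(
            [[0, 1, 2], [0, 2, 3], [1, 0, 4], [2, 1, 4], [3, 2, 4], [0, 3, 4]]
        )
        m = vt.build_mesh(pos, faces)
        params = MechanicalParams(K_v=0, K_c=0, K_r=0, kappa_act=0)
        d = vt.trial_delta(m, "flip", (0, 2), params)
        assert d == pytest.approx(0.0, abs=1e-12)


class TestRandomEventSequences:
    def test_invariants_preserved_and_cache_consistent(self):
        rng = np.random.default_rng(5)
        mesh = perturbed_icosphere(subdivisions=2, amplitude=0.03, seed=2)
        cache = MeshCache(mesh)
        applied = 0
        attempts = 0
        while applied < 400 and attempts < 20000:
            attempts += 1
            kind = ("flip", "flip", "split", "merge")[rng.integers(4)]
            k = int(rng.integers(len(cache.edges)))
            try:
                if kind == "flip":
                    _, payload = topo.flip_trial(cache, k)
                    topo.apply_flip(cache, payload)
                elif kind == "split":
                    topo.check_split(cache, k)
                    topo.apply_split(mesh, cache, k)
                    cache.rebuild_topology()
                    cache.refresh_geometry()
                else:
                    topo.check_merge(cache, k)
                    topo.apply_merge(mesh, cache, k)
                    cache.rebuild_topology()
                    cache.refresh_geometry()
            except topo.IllegalMove:
                continue
            applied += 1
            assert 2 * len(cache.edges) == 3 * mesh.n_faces
            if applied % 50 == 0:
                fresh = MeshCache(mesh)
                assert vt.euler_characteristic(mesh) == 2
                assert fresh.angle_deficits().sum() == pytest.approx(
                    4 * math.pi, abs=1e-9
                )
                # incremental flip updates must match a full rebuild
                np.testing.assert_allclose(
                    np.sort(cache.edge_theta), np.sort(fresh.edge_theta),
                    atol=1e-10,
                )
                np.testing.assert_allclose(
                    cache.vertex_M, fresh.vertex_M, atol=1e-10
                )
        assert applied == 400
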