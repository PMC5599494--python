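"""Energy terms and their analytic forces against independent oracles."""

import math

import numpy as np
import pytest

import vesiturn as vt
from vesiturn.energetics import MechanicalParams, _active_weights
from vesiturn.mesh import MeshCache
from tests.conftest import perturbed_icosphere


def brute_force_repulsion(positions, K_r, l_rep):
    """O(n^2) double-loop oracle for the pairwise guard energy."""
    total = 0.0
    n = len(positions)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(positions[i] - positions[j])
            if d < l_rep:
                total += 0.5 * K_r * (d / l_rep - 1.0) ** 2
    return total


class TestRepulsion:
    def test_zero_beyond_cutoff(self, icosa):
        params = MechanicalParams(l_rep=0.5)  # icosahedron edges ~ 1.05
        assert vt.repulsion_energy(icosa, params) == 0.0

    def test_single_pair_at_half_cutoff(self):
        params = MechanicalParams()
        pos = np.array(
            [[0, 0, 0], [params.l_rep / 2, 0, 0], [0, 50, 0], [0, 0, 50]],
            float,
        )
        mesh = vt.TriangleMesh(pos, np.array([[0, 1, 2], [0, 2, 3]]))
        assert vt.repulsion_energy(mesh, params) == pytest.approx(
            params.K_r / 8.0
        )

    def test_matches_brute_force_on_random_cloud(self):
        rng = np.random.default_rng(42)
        pos = rng.uniform(0, 3.0, size=(50, 3))
        mesh = vt.TriangleMesh(pos, np.array([[0, 1, 2]]))
        params = MechanicalParams(l_rep=1.0, K_r=7.0)
        assert vt.repulsion_energy(mesh, params) == pytest.approx(
            brute_force_repulsion(pos, 7.0, 1.0), rel=1e-12
        )


class TestEffectiveEnergy:
    def test_zero_at_equilibrium(self):
        # faces of exactly a_eq and volume exactly v_eq: only bending remains
        m = vt.tetrahedron()
        cache = MeshCache(m)
        scale = math.sqrt(1.0 / cache.face_area[0])
        m.positions *= scale
        params = MechanicalParams(v_eq=vt.enclosed_volume(m))
        u_vol, u_area, u_bend = vt.effective_energy(m, params)
        assert u_vol == pytest.approx(0.0, abs=1e-20)
        assert u_area == pytest.approx(0.0, abs=1e-12)
        assert u_bend > 0

    def test_area_term_quadratic_in_strain(self):
        # all four tetrahedron faces stretched to 1.1 a_eq
        m = vt.tetrahedron()
        cache = MeshCache(m)
        m.positions *= math.sqrt(1.1 / cache.face_area[0])
        params = MechanicalParams(v_eq=vt.enclosed_volume(m))
        _, u_area, _ = vt.effective_energy(m, params)
        assert u_area == pytest.approx(4 * 0.005 * params.K_a)

    @pytest.mark.parametrize("radius", [0.5, 1.0, 2.0])
    def test_bending_near_willmore_for_any_radius(self, radius):
        m = vt.icosphere(subdivisions=2, radius=radius)
        params = MechanicalParams(K_c=3.0, v_eq=1.0)
        _, _, u_bend = vt.effective_energy(m, params)
        assert u_bend == pytest.approx(8 * math.pi * 3.0, rel=0.02)


class TestActiveEnergy:
    def test_zero_amplitude(self, icosa):
        params = MechanicalParams(kappa_act=0.0)
        assert vt.active_energy(icosa, params, np.zeros(3)) == 0.0

    def test_octahedron_symmetry_gives_half_area(self):
        # sum of (1 + cos phi)/2 * a over a centro-symmetric mesh = A/2
        m = vt.octahedron()
        params = MechanicalParams(kappa_act=2.0)
        cache = MeshCache(m)
        u = vt.active_energy(m, params, np.zeros(3), cache)
        assert u == pytest.approx(2.0 * cache.total_area / 2.0)

    def test_angular_weights_front_and_back(self):
        centroids = np.array([[2.0, 0, 0], [-2.0, 0, 0], [0, 3.0, 0]])
        w = _active_weights(centroids, np.zeros(3))
        assert w[0] == pytest.approx(1.0)  # along +x: full weight
        assert w[1] == pytest.approx(0.0)  # along -x: none
        assert w[2] == pytest.approx(0.5)  # equator

    def test_center_coincident_with_centroid_raises(self):
        centroids = np.array([[1.0, 0, 0], [0.0, 0, 0]])
        with pytest.raises(ValueError):
            _active_weights(centroids, np.zeros(3))


def frozen_energy(mesh, params, center, weights):
    """Total energy with the active angular weights held fixed (the oracle
    consistent with how forces treat the non-conservative term)."""
    cache = MeshCache(mesh)
    u_vol, u_area, u_bend = vt.effective_energy(mesh, params, cache)
    u = u_vol + u_area + u_bend + vt.repulsion_energy(mesh, params)
    if params.kappa_act != 0.0:
        u += params.kappa_act * float(np.sum(weights * cache.face_area))
    return u


TERM_PARAMS = {
    "area": dict(K_v=0, K_a=50, K_c=0, K_r=0, kappa_act=0),
    "volume": dict(K_v=1e4, K_a=0, K_c=0, K_r=0, kappa_act=0),
    "bending": dict(K_v=0, K_a=0, K_c=3, K_r=0, kappa_act=0),
    "active": dict(K_v=0, K_a=0, K_c=0, K_r=0, kappa_act=2),
    "repulsion": dict(K_v=0, K_a=0, K_c=0, K_r=1e3, kappa_act=0, l_rep=1.6),
    "total": dict(K_v=1e4, K_a=50, K_c=3, K_r=1e3, kappa_act=2, l_rep=1.6),
}


class TestForces:
    @pytest.mark.parametrize("term", sorted(TERM_PARAMS))
    def test_matches_central_finite_differences(self, term):
        mesh = perturbed_icosphere(subdivisions=1, amplitude=0.05, seed=3)
        params = MechanicalParams(v_eq=vt.enclosed_volume(mesh) * 1.1,
                                  **TERM_PARAMS[term])
        center = vt.active_center(mesh)
        weights = _active_weights(MeshCache(mesh).face_centroid, center)
        f = vt.forces(mesh, params, active_center_point=center)
        rng = np.random.default_rng(7)
        x0 = mesh.positions.ravel()
        h = 1e-6
        idx = rng.choice(x0.size, 45, replace=False)
        for i in idx:
            for sign, store in ((1, "up"), (-1, "dn")):
                x = x0.copy()
                x[i] += sign * h
                m2 = vt.TriangleMesh(x.reshape(-1, 3), mesh.faces)
                if store == "up":
                    up = frozen_energy(m2, params, center, weights)
                else:
                    dn = frozen_energy(m2, params, center, weights)
            fd = -(up - dn) / (2 * h)
            assert f.ravel()[i] == pytest.approx(
                fd, rel=1e-5, abs=1e-7
            ), f"{term} force mismatch at dof {i}"

    def test_conservative_terms_have_zero_net_force(self, bumpy_sphere):
        params = MechanicalParams(K_c=3.0, v_eq=200.0, kappa_act=0.0)
        f = vt.forces(bumpy_sphere, params)
        assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_volume_deficit_pushes_outward(self):
        mesh = vt.icosphere(subdivisions=1, radius=1.0)
        vol = vt.enclosed_volume(mesh)
        params = MechanicalParams(
            K_v=1e4, v_eq=2 * vol, K_a=0, K_c=0, K_r=0, kappa_act=0
        )
        f = vt.forces(mesh, params)
        radial = np.einsum("ij,ij->i", f, mesh.positions)
        assert np.all(radial > 0)

    def test_energy_decreases_under_noiseless_descent(self, bumpy_sphere):
        mesh = bumpy_sphere.copy()
        params = MechanicalParams(K_c=3.0, v_eq=vt.enclosed_volume(mesh))
        dt = 1e-4
        u_prev = vt.total_energy(mesh, params)
        for _ in range(50):
            f = vt.forces(mesh, params)
            mesh.positions = mesh.positions + (dt / params.eta) * f
            u = vt.total_energy(mesh, params)
            assert u <= u_prev + 1e-12
            u_prev = u
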