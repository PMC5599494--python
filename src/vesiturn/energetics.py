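"""Membrane energy function and its analytic per-vertex forces.

The total energy is ``U = U_cc + U_eff + U_act``:

* ``U_cc`` — short-ranged pairwise vertex repulsion that keeps the
  triangulation from collapsing (numerical excluded volume),
* ``U_eff`` — volume elasticity of the vesicle, area elasticity per
  triangle, and Julicher-type discrete bending energy
  ``sum_i 2 K_c M_i^2 / A_i``,
* ``U_act`` — an optional, locally biased cortical surface tension
  ``sum_f kappa_act (1 + cos phi_f)/2 * a_f`` with ``phi_f`` the polar angle
  of the face centroid about the +x axis seen from the vesicle center;
  ``phi_f`` is frozen during force evaluation, which makes the term
  non-conservative and drives migration.

Forces are exact gradients (area, volume, edge length and dihedral-angle
derivatives in closed form), vectorized over the whole mesh; a central
finite-difference oracle in the test-suite pins them down term by term.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .mesh import MeshCache, TriangleMesh

__all__ = [
    "MechanicalParams",
    "EnergyBreakdown",
    "default_l_rep",
    "repulsion_energy",
    "effective_energy",
    "active_energy",
    "energy_breakdown",
    "total_energy",
    "forces",
    "active_center",
]


def default_l_rep(a_eq: float = 1.0) -> float:
    """Half the side of the equilateral triangle of area ``a_eq``.

    Below the minimum vertex spacing of any regular fan of equal-area
    triangles, so relaxed packings are repulsion-free, while a vertex
    inserted on a short edge still feels the guard.
    """
    return float(0.5 * np.sqrt(4.0 * a_eq / np.sqrt(3.0)))


@dataclass(frozen=True)
class MechanicalParams:
    """Mechanical constants in model units (``l = sqrt(a_eq)``, ``k_BT = 1``).

    Defaults are the reference parameter set used throughout: stiff volume
    constraint ``K_v = 1e4``, area elasticity ``K_a = 50``, bending rigidity
    ``K_c`` of order 1-10, repulsive modulus ``K_r = 1e3``, and the friction
    ``eta = 10`` implied by the time unit ``tau = 0.1 * eta * a_eq / k_BT``.
    """

    K_v: float = 1.0e4
    v_eq: float = 2527.0
    K_a: float = 50.0
    a_eq: float = 1.0
    K_c: float = 10.0
    K_r: float = 1.0e3
    l_rep: float = default_l_rep()
    kappa_act: float = 0.0
    eta: float = 10.0
    kBT: float = 1.0

    def __post_init__(self):
        for name in ("K_v", "K_a", "K_c", "K_r", "kappa_act"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.l_rep <= 0 or self.a_eq <= 0 or self.v_eq <= 0:
            raise ValueError("l_rep, a_eq and v_eq must be positive")
        if self.eta <= 0 or self.kBT < 0:
            raise ValueError("eta must be positive and kBT non-negative")

    def replace(self, **kw) -> "MechanicalParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy decomposition in units of ``k_BT``."""

    U_cc: float
    U_volume: float
    U_area: float
    U_bending: float
    U_act: float

    @property
    def U_total(self) -> float:
        return self.U_cc + self.U_volume + self.U_area + self.U_bending + self.U_act

    def as_dict(self) -> dict:
        return {
            "U_cc": self.U_cc,
            "U_volume": self.U_volume,
            "U_area": self.U_area,
            "U_bending": self.U_bending,
            "U_act": self.U_act,
            "U_total": self.U_total,
        }


def _cache(mesh: TriangleMesh, cache: MeshCache | None) -> MeshCache:
    return cache if cache is not None else MeshCache(mesh)


# ---------------------------------------------------------------------------
# Energies


def repulsion_pairs(positions: np.ndarray, l_rep: float):
    """Index pairs (i < j) with separation strictly below ``l_rep``."""
    tree = cKDTree(positions)
    pairs = tree.query_pairs(l_rep, output_type="ndarray")
    if pairs.size == 0:
        return pairs.reshape(0, 2), np.empty(0)
    d = np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]], axis=1)
    keep = d < l_rep
    return pairs[keep], d[keep]


def repulsion_energy(mesh: TriangleMesh, params: MechanicalParams) -> float:
    """Pairwise guard energy; zero when all vertices are at least l_rep apart."""
    _, d = repulsion_pairs(mesh.positions, params.l_rep)
    if d.size == 0:
        return 0.0
    return float(np.sum(0.5 * params.K_r * (d / params.l_rep - 1.0) ** 2))


def effective_energy(
    mesh: TriangleMesh, params: MechanicalParams, cache: MeshCache | None = None
):
    """Return ``(U_volume, U_area, U_bending)``."""
    c = _cache(mesh, cache)
    u_vol = 0.5 * params.K_v * (c.total_volume / params.v_eq - 1.0) ** 2
    u_area = float(
        np.sum(0.5 * params.K_a * (c.face_area / params.a_eq - 1.0) ** 2)
    )
    if np.any(c.vertex_A <= 0):
        raise ValueError("degenerate vertex with zero surrounding area")
    u_bend = float(np.sum(2.0 * params.K_c * c.vertex_M**2 / c.vertex_A))
    return u_vol, u_area, u_bend


def active_center(mesh: TriangleMesh, cache: MeshCache | None = None) -> np.ndarray:
    """Vesicle center: area-weighted mean of face centroids."""
    c = _cache(mesh, cache)
    return np.asarray(
        (c.face_area[:, None] * c.face_centroid).sum(axis=0) / c.total_area
    )


def _active_weights(centroids: np.ndarray, center: np.ndarray) -> np.ndarray:
    rel = centroids - center
    rn = np.linalg.norm(rel, axis=1)
    if np.any(rn == 0):
        raise ValueError("face centroid coincides with the vesicle center")
    cos_phi = rel[:, 0] / rn
    return 0.5 * (1.0 + cos_phi)


def active_energy(
    mesh: TriangleMesh,
    params: MechanicalParams,
    center: np.ndarray,
    cache: MeshCache | None = None,
) -> float:
    """Biased cortical tension with the angular weight frozen at ``center``."""
    if params.kappa_act == 0.0:
        return 0.0
    c = _cache(mesh, cache)
    w = _active_weights(c.face_centroid, np.asarray(center, dtype=float))
    return float(params.kappa_act * np.sum(w * c.face_area))


def energy_breakdown(
    mesh: TriangleMesh,
    params: MechanicalParams,
    center: np.ndarray | None = None,
    cache: MeshCache | None = None,
) -> EnergyBreakdown:
    c = _cache(mesh, cache)
    u_vol, u_area, u_bend = effective_energy(mesh, params, c)
    u_cc = repulsion_energy(mesh, params)
    if params.kappa_act != 0.0:
        if center is None:
            center = active_center(mesh, c)
        u_act = active_energy(mesh, params, center, c)
    else:
        u_act = 0.0
    return EnergyBreakdown(u_cc, u_vol, u_area, u_bend, u_act)


def total_energy(
    mesh: TriangleMesh,
    params: MechanicalParams,
    center: np.ndarray | None = None,
    cache: MeshCache | None = None,
) -> float:
    return energy_breakdown(mesh, params, center, cache).U_total


# ---------------------------------------------------------------------------
# Analytic forces


def _face_area_gradients(pos, faces, normals):
    """Per-corner area gradients: grad_{r0} a = 0.5 * n_hat x (r2 - r1)."""
    r0 = pos[faces[:, 0]]
    r1 = pos[faces[:, 1]]
    r2 = pos[faces[:, 2]]
    g0 = 0.5 * np.cross(normals, r2 - r1)
    g1 = 0.5 * np.cross(normals, r0 - r2)
    g2 = 0.5 * np.cross(normals, r1 - r0)
    return g0, g1, g2


def forces(
    mesh: TriangleMesh,
    params: MechanicalParams,
    active_center_point: np.ndarray | None = None,
    cache: MeshCache | None = None,
) -> np.ndarray:
    """Exact ``-dU/dr_i`` for every vertex, shape (V, 3).

    The active-tension angular weight is held constant (evaluated at
    ``active_center_point``), so only the face areas are differentiated in
    that term, matching its per-time-step freezing in the dynamics.
    """
    c = _cache(mesh, cache)
    pos = mesh.positions
    faces = mesh.faces
    nv = mesh.n_vertices
    grad = np.zeros((nv, 3))

    # --- per-face terms sharing the area gradient -------------------------
    g0, g1, g2 = _face_area_gradients(pos, faces, c.face_normal)
    # area elasticity
    w_face = params.K_a * (c.face_area / params.a_eq - 1.0) / params.a_eq
    # active tension (frozen weight)
    if params.kappa_act != 0.0:
        if active_center_point is None:
            active_center_point = active_center(mesh, c)
        w_face = w_face + params.kappa_act * _active_weights(
            c.face_centroid, np.asarray(active_center_point, dtype=float)
        )
    # bending vertex-area part: -sum_i 2 K_c (M_i/A_i)^2 * (1/3) grad a_f
    mi_over_ai_sq = (c.vertex_M / c.vertex_A) ** 2
    beta = (
        -2.0
        * params.K_c
        / 3.0
        * (
            mi_over_ai_sq[faces[:, 0]]
            + mi_over_ai_sq[faces[:, 1]]
            + mi_over_ai_sq[faces[:, 2]]
        )
    )
    w_all = w_face + beta
    np.add.at(grad, faces[:, 0], w_all[:, None] * g0)
    np.add.at(grad, faces[:, 1], w_all[:, None] * g1)
    np.add.at(grad, faces[:, 2], w_all[:, None] * g2)

    # --- volume elasticity -------------------------------------------------
    wv = params.K_v * (c.total_volume / params.v_eq - 1.0) / params.v_eq
    if wv != 0.0:
        r0 = pos[faces[:, 0]]
        r1 = pos[faces[:, 1]]
        r2 = pos[faces[:, 2]]
        np.add.at(grad, faces[:, 0], (wv / 6.0) * np.cross(r1, r2))
        np.add.at(grad, faces[:, 1], (wv / 6.0) * np.cross(r2, r0))
        np.add.at(grad, faces[:, 2], (wv / 6.0) * np.cross(r0, r1))

    # --- bending edge part: gamma_j * grad(l_j * theta_j) -------------------
    interior = c.edge_faces[:, 1] >= 0
    iu = c.edges[interior, 0]
    iv = c.edges[interior, 1]
    m_over_a = c.vertex_M / c.vertex_A
    gamma = params.K_c * (m_over_a[iu] + m_over_a[iv])  # = 2Kc*2M/A * 1/4 summed
    p0 = pos[iu]
    p1 = pos[iv]
    p2 = pos[c.edge_opp[interior, 0]]
    p3 = pos[c.edge_opp[interior, 1]]
    e = p1 - p0
    elen = c.edge_length[interior]
    e_hat = e / elen[:, None]
    n1 = np.cross(p1 - p0, p2 - p0)
    n2 = np.cross(p0 - p1, p3 - p1)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    n1h = n1 / n1sq[:, None]
    n2h = n2 / n2sq[:, None]
    # dihedral-angle gradients (signed convention matches MeshCache.edge_theta)
    gth2 = -elen[:, None] * n1h
    gth3 = -elen[:, None] * n2h
    c11 = -np.einsum("ij,ij->i", p2 - p1, e_hat)
    c12 = -np.einsum("ij,ij->i", p3 - p1, e_hat)
    c21 = np.einsum("ij,ij->i", p2 - p0, e_hat)
    c22 = np.einsum("ij,ij->i", p3 - p0, e_hat)
    gth0 = c11[:, None] * n1h + c12[:, None] * n2h
    gth1 = c21[:, None] * n1h + c22[:, None] * n2h
    theta = c.edge_theta[interior]
    gl = gamma[:, None]
    lcol = elen[:, None]
    tcol = theta[:, None]
    np.add.at(grad, iu, gl * (-tcol * e_hat + lcol * gth0))
    np.add.at(grad, iv, gl * (tcol * e_hat + lcol * gth1))
    np.add.at(grad, c.edge_opp[interior, 0], gl * lcol * gth2)
    np.add.at(grad, c.edge_opp[interior, 1], gl * lcol * gth3)

    # --- repulsion ----------------------------------------------------------
    pairs, d = repulsion_pairs(pos, params.l_rep)
    if d.size:
        coef = params.K_r * (d / params.l_rep - 1.0) / params.l_rep
        dvec = (pos[pairs[:, 0]] - pos[pairs[:, 1]]) / d[:, None]
        np.add.at(grad, pairs[:, 0], coef[:, None] * dvec)
        np.add.at(grad, pairs[:, 1], -coef[:, None] * dvec)

    f = -grad
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite force encountered")
    return f
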