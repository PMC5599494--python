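"""Initial-condition generation and mesh fixtures.

The reference initial state is a single vesicle of exactly ``F`` triangles
(1000 by default) on a sphere scaled to total area ``F * a_eq``, then
equilibrated by noiseless relaxation and downhill edge flips at bending
rigidity ``K_c = 10`` with turnover off.  Because icosphere subdivision
cannot reach arbitrary even face counts, the generator places
``V = F/2 + 2`` points on a Fibonacci lattice and takes their convex hull,
which is a closed genus-0 triangulation with exactly ``2V - 4 = F`` faces.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import ConvexHull

from . import topology as topo
from .energetics import MechanicalParams, forces, total_energy
from .mesh import MeshCache, TriangleMesh, build_mesh

__all__ = [
    "tetrahedron",
    "octahedron",
    "icosahedron",
    "icosphere",
    "planar_patch",
    "fibonacci_sphere_mesh",
    "relax_mesh",
    "generate_vesicle",
]


def tetrahedron(scale: float = 1.0) -> TriangleMesh:
    """Regular tetrahedron (4 vertices, 4 faces)."""
    pos = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) * (scale / math.sqrt(3.0))
    faces = [[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]]
    return build_mesh(pos, _oriented(pos, faces))


def octahedron(scale: float = 1.0) -> TriangleMesh:
    """Regular octahedron (6 vertices, 8 faces)."""
    pos = scale * np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    faces = [
        [0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
        [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5],
    ]
    return build_mesh(pos, _oriented(pos, faces))


def icosahedron(scale: float = 1.0) -> TriangleMesh:
    """Regular icosahedron (12 vertices, 20 faces, 30 edges)."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    pos = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    pos *= scale / np.linalg.norm(pos[0])
    faces = [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ]
    return build_mesh(pos, _oriented(pos, faces))


def icosphere(subdivisions: int = 1, radius: float = 1.0) -> TriangleMesh:
    """Icosahedron subdivided ``n`` times and projected onto the sphere."""
    mesh = icosahedron()
    pos = mesh.positions
    faces = mesh.faces
    for _ in range(subdivisions):
        pos, faces = _subdivide(pos, faces)
    pos = pos / np.linalg.norm(pos, axis=1)[:, None] * radius
    return build_mesh(pos, faces)


def _subdivide(pos, faces):
    midpoint = {}
    new_pos = [tuple(p) for p in pos]

    def mid(a, b):
        key = (a, b) if a < b else (b, a)
        if key not in midpoint:
            midpoint[key] = len(new_pos)
            new_pos.append(tuple(0.5 * (pos[a] + pos[b])))
        return midpoint[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
    return np.array(new_pos), np.array(new_faces, dtype=np.int64)


def planar_patch(n: int = 4, jitter: float = 0.0, seed: int = 0) -> TriangleMesh:
    """Open flat n x n grid patch (geometry unit tests only)."""
    rng = np.random.default_rng(seed)
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    pos = np.stack([xs.ravel(), ys.ravel(), np.zeros(n * n)], axis=1)
    if jitter:
        pos[:, :2] += jitter * rng.standard_normal((n * n, 2))
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
    return build_mesh(pos, np.array(faces), allow_boundary=True)


def _oriented(pos, faces):
    """Wind faces of a star-shaped closed surface outward from the centroid."""
    faces = np.asarray(faces, dtype=np.int64)
    c = np.asarray(pos).mean(axis=0)
    r0, r1, r2 = (np.asarray(pos)[faces[:, i]] for i in range(3))
    n = np.cross(r1 - r0, r2 - r0)
    flip = np.einsum("ij,ij->i", n, (r0 + r1 + r2) / 3.0 - c) < 0
    faces[flip] = faces[flip][:, ::-1]
    return faces


def fibonacci_sphere_mesh(
    face_count: int, radius: float = 1.0, seed: int = 0
) -> TriangleMesh:
    """Closed triangulation with exactly ``face_count`` faces on a sphere.

    ``face_count`` must be even and >= 20; the convex hull of
    ``V = face_count/2 + 2`` generic points on the sphere has exactly
    ``2V - 4`` triangular faces.
    """
    if face_count % 2 != 0 or face_count < 20:
        raise ValueError("face_count must be an even integer >= 20")
    n = face_count // 2 + 2
    rng = np.random.default_rng(seed)
    i = np.arange(n, dtype=float)
    # golden-angle spiral; tiny jitter avoids degenerate hull facets
    ga = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = ga * i + 1e-4 * rng.standard_normal(n)
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = radius * np.stack(
        [r * np.cos(theta), r * np.sin(theta), z], axis=1
    )
    hull = ConvexHull(pts)
    if hull.simplices.shape[0] != face_count:
        raise RuntimeError(
            f"hull produced {hull.simplices.shape[0]} faces, "
            f"expected {face_count}"
        )
    return build_mesh(pts, _oriented(pts, hull.simplices))


def relax_mesh(
    mesh: TriangleMesh,
    params: MechanicalParams,
    tol: float = 1.0e-6,
    max_cycles: int = 40,
    maxiter: int = 400,
    theta_guard: float = 2.5,
    gate: topo.QualityGate = topo.DEFAULT_GATE,
) -> TriangleMesh:
    """Noiseless relaxation: L-BFGS descent alternating with downhill flips.

    All energy terms are conservative here (no active tension), so the
    quasi-Newton minimizer with the analytic gradient handles the stiff
    volume constraint efficiently.  Cycles of descent + greedy flip sweeps
    repeat until a cycle accepts no flip and lowers the energy by less than
    ``tol`` per descent step.  Deterministic.

    The vertex-based bending measure cancels on zigzag pleats, so deep
    noiseless descent of a strongly deflated vesicle can fold the surface
    isometrically into creases that thermal dynamics would never sustain;
    a cycle whose maximum dihedral angle exceeds ``theta_guard`` is
    reverted and the relaxation stops at the last smooth iterate.
    """
    from scipy.optimize import minimize

    cache = MeshCache(mesh)

    def fun(x):
        mesh.positions = x.reshape(-1, 3)
        cache.refresh_geometry()
        u = total_energy(mesh, params, cache=cache)
        g = -forces(mesh, params, cache=cache)
        return u, g.ravel()

    u_prev = total_energy(mesh, params, cache=cache)
    for _cycle in range(max_cycles):
        saved = mesh.positions.copy()
        res = minimize(
            fun,
            mesh.positions.ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-9},
        )
        mesh.positions = res.x.reshape(-1, 3)
        cache.refresh_geometry()
        if np.abs(cache.edge_theta).max() > theta_guard:
            mesh.positions = saved
            cache.refresh_geometry()
            break
        n_flips = _downhill_flips(mesh, cache, params, gate)
        u_new = total_energy(mesh, params, cache=cache)
        if n_flips == 0 and u_prev - u_new < tol * max(1, res.nit):
            break
        u_prev = u_new
    return mesh


def _downhill_flips(mesh, cache, params, gate) -> int:
    """Greedy pass: apply every flip that strictly lowers the energy."""
    total = 0
    for _pass in range(30):
        accepted = 0
        for k in range(len(cache.edges)):
            try:
                d_u, payload = topo.flip_trial(cache, k, params, gate=gate)
            except topo.IllegalMove:
                continue
            if d_u < -1e-12:
                topo.apply_flip(cache, payload)
                accepted += 1
        total += accepted
        if accepted == 0:
            break
    return total


def generate_vesicle(
    face_count: int,
    sphericity: float = 0.85,
    params: MechanicalParams | None = None,
    seed: int = 0,
    tol: float = 1.0e-6,
) -> TriangleMesh:
    """Equilibrated closed vesicle with exactly ``face_count`` triangles.

    The initial state is the sphere of total area ``face_count * a_eq``
    (this is where the reference area trace starts), with the triangulation
    regularized by noiseless relaxation and downhill flips at bending
    rigidity ``K_c = 10``, turnover off, and the volume constraint centered
    on the sphere's own volume so equilibration reshuffles the mesh without
    deflating it.  ``sphericity`` does not alter this initial geometry; it
    parameterizes the equilibrium volume ``v_eq`` that the subsequent
    dynamics relax toward (0.85 reproduces v_eq = 2527 at 1000 faces).
    """
    if params is None:
        params = MechanicalParams()
    area_target = face_count * params.a_eq
    radius = math.sqrt(area_target / (4.0 * math.pi))
    mesh = fibonacci_sphere_mesh(face_count, radius=radius, seed=seed)
    # exact area rescale (hull area is slightly below the sphere's)
    cache = MeshCache(mesh)
    mesh.positions *= math.sqrt(area_target / cache.total_area)
    cache.refresh_geometry()
    params = params.replace(K_c=10.0, v_eq=cache.total_volume, kappa_act=0.0)
    relax_mesh(mesh, params, tol=tol)
    return mesh
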