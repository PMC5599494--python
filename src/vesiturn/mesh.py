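"""Manifold triangle meshes and the discrete geometry consumed by the energies.

A vesicle is represented by a closed, outward-oriented, genus-0 triangulation.
Vertex positions carry the membrane shape; connectivity carries its topology,
which the flip/split/merge moves rewrite at run time.  All discrete geometric
quantities (face areas and normals, edge lengths and signed dihedral angles,
per-vertex total mean curvature ``M_i = sum_j l_j * theta_j / 4`` and vertex
area ``A_i = sum_j a_j / 3``) live in :class:`MeshCache`, which is rebuilt
vectorized after every integration step and patched incrementally after edge
flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriangleMesh",
    "MeshCache",
    "MeshError",
    "NonManifoldError",
    "OrientationError",
    "DuplicateFaceError",
    "DegenerateFaceError",
    "OpenMeshError",
    "build_mesh",
    "enclosed_volume",
    "edge_dihedral_angle",
    "vertex_curvature_measures",
    "euler_characteristic",
]


class MeshError(ValueError):
    """Base class for mesh validation failures."""


class NonManifoldError(MeshError):
    """An edge is shared by a number of faces different from two."""


class OrientationError(MeshError):
    """Face windings are inconsistent and cannot be repaired globally."""


class DuplicateFaceError(MeshError):
    """The same vertex triple appears more than once."""


class DegenerateFaceError(MeshError):
    """A face has zero area or a repeated vertex."""


class OpenMeshError(MeshError):
    """Operation requires a closed surface but the mesh has boundary."""


@dataclass
class TriangleMesh:
    """Triangle mesh given by vertex positions and oriented face triples.

    Parameters
    ----------
    positions : (V, 3) float array
        Vertex coordinates in model units (unit length ``l = sqrt(a_eq)``).
    faces : (F, 3) int array
        Vertex index triples, wound consistently; for a closed mesh the
        orientation is outward (positive enclosed volume).
    """

    positions: np.ndarray
    faces: np.ndarray

    @property
    def n_vertices(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.positions.copy(), self.faces.copy())


def _directed_edges(faces: np.ndarray):
    """Return (3F, 2) directed edge array in face winding order."""
    return np.stack(
        [faces[:, [0, 1, 2]].ravel(), faces[:, [1, 2, 0]].ravel()], axis=1
    )


def build_mesh(
    positions, faces, *, allow_boundary: bool = False, validate: bool = True
) -> TriangleMesh:
    """Validate and orient a triangle mesh.

    Checks manifoldness (every edge on exactly two faces), consistent
    winding, absence of duplicate or degenerate faces, and normalizes the
    global orientation so the enclosed volume is positive.  Open patches are
    admitted only with ``allow_boundary=True`` (geometry unit tests); the
    simulator itself always runs on closed surfaces.
    """
    positions = np.ascontiguousarray(positions, dtype=np.float64)
    faces = np.ascontiguousarray(faces, dtype=np.int64)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise MeshError("positions must be an (V, 3) array")
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MeshError("faces must be an (F, 3) array")
    if positions.shape[0] < 4:
        raise MeshError("a triangulated surface needs at least 4 vertices")
    if faces.min(initial=0) < 0 or faces.max(initial=-1) >= positions.shape[0]:
        raise MeshError("face indices out of range")
    mesh = TriangleMesh(positions, faces)
    if not validate:
        return mesh

    if np.any(
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 2] == faces[:, 0])
    ):
        raise DegenerateFaceError("face with a repeated vertex")

    canon = np.sort(faces, axis=1)
    if np.unique(canon, axis=0).shape[0] != faces.shape[0]:
        raise DuplicateFaceError("duplicate face (same vertex triple twice)")

    de = _directed_edges(faces)
    lo = np.minimum(de[:, 0], de[:, 1])
    hi = np.maximum(de[:, 0], de[:, 1])
    key = lo * np.int64(positions.shape[0]) + hi
    uniq, counts = np.unique(key, return_counts=True)
    if allow_boundary:
        if np.any(counts > 2):
            raise NonManifoldError("edge shared by more than two faces")
    else:
        if np.any(counts != 2):
            bad = int(uniq[np.argmax(counts != 2)])
            raise NonManifoldError(
                f"edge {divmod(bad, positions.shape[0])} lies on "
                f"{int(counts[np.argmax(counts != 2)])} faces, expected 2"
            )
    # Winding consistency: a shared undirected edge must be traversed once in
    # each direction.  Equal directed duplicates mean inconsistent winding.
    dkey = de[:, 0] * np.int64(positions.shape[0]) + de[:, 1]
    if np.unique(dkey).shape[0] != dkey.shape[0]:
        raise OrientationError(
            "two faces traverse a shared edge in the same direction"
        )

    if not allow_boundary:
        vol = _signed_volume(positions, faces)
        if vol < 0:
            mesh.faces = faces[:, ::-1].copy()
        elif vol == 0:
            raise DegenerateFaceError("mesh encloses zero volume")
    return mesh


def _signed_volume(positions: np.ndarray, faces: np.ndarray) -> float:
    r0 = positions[faces[:, 0]]
    r1 = positions[faces[:, 1]]
    r2 = positions[faces[:, 2]]
    return float(np.einsum("ij,ij->", r0, np.cross(r1, r2)) / 6.0)


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Signed enclosed volume by the divergence theorem (positive outward)."""
    de = _directed_edges(mesh.faces)
    dkey = de[:, 0] * np.int64(mesh.n_vertices) + de[:, 1]
    lo = np.minimum(de[:, 0], de[:, 1])
    hi = np.maximum(de[:, 0], de[:, 1])
    key = lo * np.int64(mesh.n_vertices) + hi
    _, counts = np.unique(key, return_counts=True)
    if np.any(counts != 2):
        raise OpenMeshError("enclosed volume undefined for an open mesh")
    del dkey
    return _signed_volume(mesh.positions, mesh.faces)


def euler_characteristic(mesh: TriangleMesh) -> int:
    """V - E + F; equals 2 for a closed genus-0 surface."""
    de = _directed_edges(mesh.faces)
    lo = np.minimum(de[:, 0], de[:, 1])
    hi = np.maximum(de[:, 0], de[:, 1])
    n_edges = np.unique(lo * np.int64(mesh.n_vertices) + hi).shape[0]
    n_verts = np.unique(mesh.faces).shape[0]
    return int(n_verts - n_edges + mesh.n_faces)


# ---------------------------------------------------------------------------
# Geometry + adjacency cache


@dataclass
class MeshCache:
    """Derived adjacency and per-element geometry for a mesh.

    Topology arrays (edges, incident faces, opposite vertices, vertex
    adjacency sets) are rebuilt after split/merge events; geometry arrays are
    refreshed vectorized after every position update and patched in place
    after accepted flips.

    Edge convention: ``edges[k] = (u, v)`` with ``edge_faces[k, 0]`` the face
    traversing ``u -> v`` and ``edge_faces[k, 1]`` the face traversing
    ``v -> u`` (``-1`` on a boundary).  The signed dihedral ``theta[k]`` is
    positive where the surface is locally convex (outward normals diverge).
    """

    mesh: TriangleMesh
    allow_boundary: bool = False

    # topology
    edges: np.ndarray = field(init=False)
    edge_faces: np.ndarray = field(init=False)
    edge_opp: np.ndarray = field(init=False)
    vertex_neighbors: list = field(init=False)
    vertex_edges: list = field(init=False)
    vertex_faces: list = field(init=False)
    edge_index: dict = field(init=False)

    # geometry
    face_area: np.ndarray = field(init=False)
    face_normal: np.ndarray = field(init=False)
    face_centroid: np.ndarray = field(init=False)
    edge_length: np.ndarray = field(init=False)
    edge_theta: np.ndarray = field(init=False)
    vertex_M: np.ndarray = field(init=False)
    vertex_A: np.ndarray = field(init=False)
    total_area: float = field(init=False)
    total_volume: float = field(init=False)
    pos_list: list = field(init=False)

    def __post_init__(self):
        self.rebuild_topology()
        self.refresh_geometry()

    # -- topology -----------------------------------------------------------

    def rebuild_topology(self) -> None:
        mesh = self.mesh
        faces = mesh.faces
        nv = mesh.n_vertices
        de = _directed_edges(faces)
        opp = faces[:, [2, 0, 1]].ravel()
        face_of = np.repeat(np.arange(faces.shape[0], dtype=np.int64), 3)
        lo = np.minimum(de[:, 0], de[:, 1])
        hi = np.maximum(de[:, 0], de[:, 1])
        key = lo * np.int64(nv) + hi
        order = np.argsort(key, kind="stable")
        key_s = key[order]
        boundary_mode = self.allow_boundary
        if boundary_mode:
            uniq, first, counts = np.unique(
                key_s, return_index=True, return_counts=True
            )
            if np.any(counts > 2):
                raise NonManifoldError("edge shared by more than two faces")
            ne = uniq.shape[0]
            edges = np.empty((ne, 2), dtype=np.int64)
            edge_faces = np.full((ne, 2), -1, dtype=np.int64)
            edge_opp = np.full((ne, 2), -1, dtype=np.int64)
            for k in range(ne):
                for i in range(counts[k]):
                    h = order[first[k] + i]
                    u, v = de[h]
                    slot = 0 if u < v else 1
                    edges[k] = (u, v) if u < v else (v, u)
                    if edge_faces[k, slot] != -1:
                        raise OrientationError(
                            "two faces traverse a shared edge in the same "
                            "direction"
                        )
                    edge_faces[k, slot] = face_of[h]
                    edge_opp[k, slot] = opp[h]
        else:
            if key_s.shape[0] % 2 or np.any(key_s[0::2] != key_s[1::2]):
                raise NonManifoldError("edge not shared by exactly two faces")
            h0 = order[0::2]
            h1 = order[1::2]
            ne = h0.shape[0]
            # slot 0 holds the face traversing the canonical (u < v) direction
            s0 = (de[h0, 0] > de[h0, 1]).astype(np.int64)
            s1 = (de[h1, 0] > de[h1, 1]).astype(np.int64)
            if np.any(s0 == s1):
                raise OrientationError(
                    "two faces traverse a shared edge in the same direction"
                )
            edges = np.stack([lo[h0], hi[h0]], axis=1)
            edge_faces = np.empty((ne, 2), dtype=np.int64)
            edge_opp = np.empty((ne, 2), dtype=np.int64)
            idx = np.arange(ne)
            edge_faces[idx, s0] = face_of[h0]
            edge_opp[idx, s0] = opp[h0]
            edge_faces[idx, s1] = face_of[h1]
            edge_opp[idx, s1] = opp[h1]
        self.edges = edges
        self.edge_faces = edge_faces
        self.edge_opp = edge_opp
        self.valence = np.bincount(edges.ravel(), minlength=nv)

        edges_l = edges.tolist()
        self.vertex_neighbors = [set() for _ in range(nv)]
        self.vertex_edges = [set() for _ in range(nv)]
        self.vertex_faces = [set() for _ in range(nv)]
        self.edge_index = {}
        edge_index = self.edge_index
        vn = self.vertex_neighbors
        ve = self.vertex_edges
        for k, (u, v) in enumerate(edges_l):
            vn[u].add(v)
            vn[v].add(u)
            ve[u].add(k)
            ve[v].add(k)
            edge_index[(u, v)] = k
        vf = self.vertex_faces
        for f, (a, b, c) in enumerate(faces.tolist()):
            vf[a].add(f)
            vf[b].add(f)
            vf[c].add(f)

    def edge_id(self, u: int, v: int) -> int:
        """Edge index for an unordered vertex pair; KeyError if absent."""
        return self.edge_index[(u, v) if u < v else (v, u)]

    # -- geometry -----------------------------------------------------------

    def refresh_geometry(self) -> None:
        mesh = self.mesh
        pos = mesh.positions
        faces = mesh.faces
        r0 = pos[faces[:, 0]]
        r1 = pos[faces[:, 1]]
        r2 = pos[faces[:, 2]]
        n = np.cross(r1 - r0, r2 - r0)
        nn = np.linalg.norm(n, axis=1)
        if np.any(nn == 0):
            raise DegenerateFaceError("zero-area face")
        self.face_area = 0.5 * nn
        self.face_normal = n / nn[:, None]
        self.face_centroid = (r0 + r1 + r2) / 3.0
        self.total_volume = float(np.einsum("ij,ij->", r0, np.cross(r1, r2)) / 6.0)
        self.total_area = float(self.face_area.sum())

        eu = pos[self.edges[:, 0]]
        ev = pos[self.edges[:, 1]]
        evec = ev - eu
        self.edge_length = np.linalg.norm(evec, axis=1)
        interior = self.edge_faces[:, 1] >= 0
        theta = np.zeros(self.edges.shape[0])
        if np.any(interior):
            f0 = self.edge_faces[interior, 0]
            f1 = self.edge_faces[interior, 1]
            n0 = self.face_normal[f0]
            n1 = self.face_normal[f1]
            e_hat = evec[interior] / self.edge_length[interior, None]
            s = np.einsum("ij,ij->i", np.cross(n0, n1), e_hat)
            c = np.einsum("ij,ij->i", n0, n1)
            theta[interior] = np.arctan2(s, c)
        self.edge_theta = theta

        nv = mesh.n_vertices
        m = np.zeros(nv)
        lt = self.edge_length * self.edge_theta / 4.0
        np.add.at(m, self.edges[:, 0], lt)
        np.add.at(m, self.edges[:, 1], lt)
        self.vertex_M = m
        a = np.zeros(nv)
        fa3 = self.face_area / 3.0
        np.add.at(a, faces[:, 0], fa3)
        np.add.at(a, faces[:, 1], fa3)
        np.add.at(a, faces[:, 2], fa3)
        self.vertex_A = a
        self.pos_list = pos.tolist()

    def angle_deficits(self) -> np.ndarray:
        """2*pi minus the sum of incident face angles, per vertex."""
        mesh = self.mesh
        pos = mesh.positions
        faces = mesh.faces
        deficits = np.full(mesh.n_vertices, 2.0 * np.pi)
        for shift in range(3):
            i = faces[:, shift]
            j = faces[:, (shift + 1) % 3]
            k = faces[:, (shift + 2) % 3]
            u = pos[j] - pos[i]
            v = pos[k] - pos[i]
            cu = np.linalg.norm(u, axis=1)
            cv = np.linalg.norm(v, axis=1)
            cosang = np.einsum("ij,ij->i", u, v) / (cu * cv)
            np.add.at(deficits, i, -np.arccos(np.clip(cosang, -1.0, 1.0)))
        # isolated vertices (none in valid meshes) carry no deficit
        used = np.zeros(mesh.n_vertices, dtype=bool)
        used[faces.ravel()] = True
        deficits[~used] = 0.0
        return deficits


# ---------------------------------------------------------------------------
# Convenience per-element queries (thin wrappers over a throwaway cache)


def edge_dihedral_angle(mesh: TriangleMesh, edge) -> float:
    """Signed dihedral angle across ``edge = (u, v)`` in (-pi, pi).

    Positive where the fold is convex seen from outside (outward face
    normals diverging); the sign flips under reflection of the surface.
    """
    cache = MeshCache(mesh, allow_boundary=True)
    k = cache.edge_id(int(edge[0]), int(edge[1]))
    if cache.edge_faces[k, 1] < 0:
        raise OpenMeshError("dihedral angle needs two incident faces")
    return float(cache.edge_theta[k])


def vertex_curvature_measures(mesh: TriangleMesh, vertex: int):
    """Return ``(M_i, A_i, angle_deficit)`` for one vertex.

    ``M_i`` is the Julicher total mean curvature ``sum_j l_j theta_j / 4``
    over incident edges, ``A_i`` the one-third barycentric vertex area, and
    the angle deficit is the discrete Gaussian-curvature measure whose total
    is ``4*pi`` on a closed genus-0 mesh (Gauss-Bonnet).  The local Gaussian
    curvature observable is ``angle_deficit / A_i``.
    """
    cache = MeshCache(mesh, allow_boundary=True)
    v = int(vertex)
    return (
        float(cache.vertex_M[v]),
        float(cache.vertex_A[v]),
        float(cache.angle_deficits()[v]),
    )
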