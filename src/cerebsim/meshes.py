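"""Triangle-mesh primitives for source-surface modeling.

All geometry is kept in SI units (meters, m^2) internally; millimeters appear
only at the user-facing recipe/config boundary.  Meshes are plain
vertex/face arrays; :mod:`trimesh` stands behind file I/O and proximity
queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import trimesh


@dataclass
class TriangleMesh:
    """A triangulated surface.

    Parameters
    ----------
    vertices : ndarray, shape (n_vertices, 3)
        Vertex positions in meters.
    faces : ndarray, shape (n_faces, 3)
        Integer triples indexing ``vertices``; consistently oriented
        (counter-clockwise seen from outside for closed shells).
    scalar : ndarray, shape (n_vertices,), optional
        A per-vertex scalar channel (e.g. a sensitivity value).
    """

    vertices: np.ndarray
    faces: np.ndarray
    scalar: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must have shape (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must have shape (m, 3)")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    # -- basic derived quantities -------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_cross(self) -> np.ndarray:
        """Unnormalized face normals ((v1-v0) x (v2-v0))."""
        tri = self.vertices[self.faces]
        return np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])

    def face_areas(self) -> np.ndarray:
        """Face areas in m^2."""
        return 0.5 * np.linalg.norm(self.face_cross(), axis=1)

    def face_normals(self) -> np.ndarray:
        """Unit face normals."""
        c = self.face_cross()
        n = np.linalg.norm(c, axis=1, keepdims=True)
        if np.any(n == 0.0):
            raise ValueError("mesh contains degenerate (zero-area) faces")
        return c / n

    def area(self) -> float:
        """Total surface area in m^2."""
        return float(self.face_areas().sum())

    def edges_unique(self) -> np.ndarray:
        """Unique undirected edges, shape (n_edges, 2), sorted pairs."""
        e = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges_unique()) + self.n_faces

    def vertex_adjacency(self) -> sp.csr_matrix:
        """Vertex adjacency graph weighted by Euclidean edge length (m)."""
        e = self.edges_unique()
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        n = self.n_vertices
        m = sp.coo_matrix(
            (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n, n),
        )
        return m.tocsr()

    def is_connected(self) -> bool:
        n_comp, _ = sp.csgraph.connected_components(self.vertex_adjacency())
        return n_comp == 1

    def validate(self) -> None:
        """Raise ``ValueError`` if invariants are violated."""
        if np.any(self.face_areas() <= 0.0):
            raise ValueError("mesh contains degenerate (zero-area) faces")
        used = np.zeros(self.n_vertices, dtype=bool)
        used[self.faces] = True
        if not used.all():
            bad = np.flatnonzero(~used)
            raise ValueError(f"isolated vertices with no incident face: {bad[:10]}")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )


# -- per-vertex quantities ---------------------------------------------------


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Angle-weighted unit vertex normals.

    The normal at a vertex is the normalized sum of incident face normals,
    each weighted by the interior angle of the face at that vertex.  This is
    the standard discrete normal for dipole orientation on a folded sheet:
    it is insensitive to how a fan of faces is triangulated.
    """
    mesh.validate()
    tri = mesh.vertices[mesh.faces]
    fn = mesh.face_normals()
    acc = np.zeros_like(mesh.vertices)
    for k in range(3):
        a = tri[:, (k + 1) % 3] - tri[:, k]
        b = tri[:, (k + 2) % 3] - tri[:, k]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cosang = np.clip((a * b).sum(1) / (na * nb), -1.0, 1.0)
        ang = np.arccos(cosang)
        np.add.at(acc, mesh.faces[:, k], ang[:, None] * fn)
    norms = np.linalg.norm(acc, axis=1)
    if np.any(norms == 0.0):
        bad = np.flatnonzero(norms == 0.0)
        raise ValueError(
            f"zero resultant normal at vertices {bad[:10]} (pathological fold)"
        )
    return acc / norms[:, None]


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex areas in m^2: one third of each incident face's area.

    Conserves total area exactly: ``vertex_areas.sum() == face_areas.sum()``.
    """
    fa = mesh.face_areas() / 3.0
    out = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(out, mesh.faces[:, k], fa)
    return out


# -- constructions -----------------------------------------------------------


def generate_sphere_shell(radius_mm: float, subdivisions: int = 3) -> TriangleMesh:
    """Icosphere of the given radius (used for head-compartment boundaries).

    Parameters
    ----------
    radius_mm : float
        Sphere radius in millimeters.
    subdivisions : int
        Number of icosahedron subdivision levels (0 gives the icosahedron).
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(tm.vertices)
    # icosphere vertices are normalized; enforce exact radius
    v = v / np.linalg.norm(v, axis=1, keepdims=True) * (radius_mm * 1e-3)
    return TriangleMesh(v, np.asarray(tm.faces))


def _subdivide_on_sphere(vertices: np.ndarray, faces: np.ndarray):
    """One midpoint 4:1 subdivision step with reprojection to the unit sphere."""
    e = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, inv = np.unique(e, axis=0, return_inverse=True)
    mid = vertices[uniq[:, 0]] + vertices[uniq[:, 1]]
    mid /= np.linalg.norm(mid, axis=1, keepdims=True)
    mid_idx = len(vertices) + np.arange(len(uniq))
    m01, m12, m20 = (
        mid_idx[inv[0::3]],
        mid_idx[inv[1::3]],
        mid_idx[inv[2::3]],
    )
    f0, f1, f2 = faces[:, 0], faces[:, 1], faces[:, 2]
    new_faces = np.concatenate(
        [
            np.stack([f0, m01, m20], 1),
            np.stack([m01, f1, m12], 1),
            np.stack([m20, m12, f2], 1),
            np.stack([m01, m12, m20], 1),
        ]
    )
    return np.concatenate([vertices, mid]), new_faces


def _crop_cap(vertices, faces, axis, cos_limit, keep_partial=False):
    """Keep faces of a unit-sphere mesh inside the cap v.axis >= cos_limit."""
    inside = vertices @ axis >= cos_limit
    keep = inside[faces].any(axis=1) if keep_partial else inside[faces].all(axis=1)
    faces = faces[keep]
    used = np.unique(faces)
    remap = np.full(len(vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return vertices[used], remap[faces]


def unit_cap_mesh(axis: np.ndarray, cap_angular_radius_deg: float,
                  max_edge_angle: float) -> TriangleMesh:
    """Quasi-uniform triangulation of a spherical cap on the unit sphere.

    Starts from a coarse icosphere, then locally subdivides only the cap
    (with a shrinking margin) until every edge subtends at most
    ``max_edge_angle`` radians.  This stays cheap even for fine meshes on
    small caps, and works for caps of any angular radius (a planar
    height-field grid would degenerate beyond ~60 degrees).
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    theta = np.deg2rad(cap_angular_radius_deg)
    tm = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    v = np.asarray(tm.vertices)
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    f = np.asarray(tm.faces)

    def _max_edge(v, f):
        e = np.sort(f[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        e = np.unique(e, axis=0)
        return float(np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1).max())

    edge = _max_edge(v, f)
    while edge > max_edge_angle:
        # crop to the cap plus a margin of a few current edge lengths
        margin = min(np.pi, theta + 3.0 * edge)
        if margin < np.pi:
            v, f = _crop_cap(v, f, axis, np.cos(margin), keep_partial=True)
        v, f = _subdivide_on_sphere(v, f)
        edge = _max_edge(v, f)
    v, f = _crop_cap(v, f, axis, np.cos(theta), keep_partial=True)
    return TriangleMesh(v, f)


# -- I/O ---------------------------------------------------------------------


def save_mesh(path, mesh: TriangleMesh) -> None:
    """Write PLY (binary little-endian) or OFF depending on extension.

    A per-vertex scalar, if present, is written to a ``<path>.csv`` sidecar
    with columns ``vertex_index,value`` and, for PLY, as the vertex
    ``quality`` property.
    """
    path = str(path)
    tm = mesh.to_trimesh()
    if path.endswith(".ply"):
        if mesh.scalar is not None:
            tm.vertex_attributes["quality"] = np.asarray(mesh.scalar, float)
        tm.export(path, encoding="binary_little_endian")
    elif path.endswith(".off"):
        tm.export(path)
    else:
        raise ValueError(f"unsupported mesh format: {path}")
    if mesh.scalar is not None:
        import pandas as pd

        pd.DataFrame(
            {
                "vertex_index": np.arange(mesh.n_vertices),
                "value": np.asarray(mesh.scalar, float),
            }
        ).to_csv(path + ".csv", index=False)


def load_mesh(path) -> TriangleMesh:
    """Read a PLY/OFF mesh written by :func:`save_mesh` (or any trimesh-readable)."""
    tm = trimesh.load(str(path), process=False)
    scalar = None
    q = tm.vertex_attributes.get("quality") if hasattr(tm, "vertex_attributes") else None
    if q is not None:
        scalar = np.asarray(q, float).ravel()
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces), scalar=scalar)
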