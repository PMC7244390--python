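"""Synthetic folded anatomy and source spaces.

The ex vivo cerebellar tessellations used in high-resolution M/EEG forward
studies are not publicly deposited, so this module generates surrogate
surfaces that reproduce the geometric mechanism driving signal cancelation:
a cortical sheet corrugated at two scales (fine folia under coarser lobular
folds) whose opposed fold walls carry nearly antiparallel dipoles.

Three surface kinds are provided:

``cerebellum-like``
    A deeply corrugated, nearly closed shell (folia wavelength 2 mm,
    amplitude 1 mm; lobules 20 mm / 3 mm) on a 25 mm sphere offset
    posterior-inferiorly, its opening facing the brainstem.  The near-closed
    topology matters: the cerebellar cortical sheet (1.5-2 m unfolded) wraps
    its whole body, so surface normals are close to isotropic at large
    scales; a one-sided cap would retain a net orientation bias equal to its
    flat vector area no matter how deeply it is folded.
``cortex-like``
    A single-scale folded cap (20 mm wavelength, 5 mm amplitude) high on a
    70 mm sphere, standing in for the cerebral cortical mantle.
``smoothed-shell``
    The cerebellum-like recipe with the folia term removed -- a surrogate
    for outer-shell segmentations that smooth over the folia.

Internally everything is SI (meters); recipe fields are in millimeters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from . import _graph
from .meshes import TriangleMesh, unit_cap_mesh, vertex_areas, vertex_normals

logger = logging.getLogger(__name__)

_KINDS = ("cerebellum-like", "cortex-like", "smoothed-shell")


@dataclass
class SurfaceRecipe:
    """Parameters of a two-scale corrugated sheet on a spherical cap.

    The radial displacement at a point with arc-length coordinate ``s``
    (along a fixed tangential/latitude axis of the cap) is::

        d(s) = lobule_amplitude * sin(2 pi s / lobule_wavelength)
             + folia_amplitude * sin(2 pi s / folia_wavelength + phase(seed))

    All lengths are in millimeters.  ``center`` offsets the cap's sphere
    from the head origin (the cerebellum sits posterior-inferiorly).
    """

    kind: str
    folia_wavelength: float = 2.0
    folia_amplitude: float = 1.0
    lobule_wavelength: float = 20.0
    lobule_amplitude: float = 3.0
    cap_center_direction: tuple = (0.0, 0.0, 1.0)
    cap_angular_radius: float = 60.0
    base_radius: float = 55.0
    edge_length: float = 0.2
    seed: int = 0
    center: tuple = (0.0, 0.0, 0.0)
    fold_style: str = "parallel"  # or "isotropic"

    def validate(self, inner_skull_radius_mm: float | None = None) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown surface kind {self.kind!r}")
        if self.fold_style not in ("parallel", "isotropic"):
            raise ValueError(f"unknown fold_style {self.fold_style!r}")
        if self.folia_wavelength <= 0 or self.lobule_wavelength <= 0:
            raise ValueError("wavelengths must be positive")
        if self.edge_length <= 0:
            raise ValueError("edge_length must be positive")
        if self.folia_amplitude > 0 and self.edge_length > self.folia_wavelength / 10:
            raise ValueError(
                f"edge_length {self.edge_length} mm cannot resolve folia of "
                f"wavelength {self.folia_wavelength} mm; need <= "
                f"{self.folia_wavelength / 10:g} mm (one tenth wavelength)"
            )
        if self.lobule_amplitude > 0 and self.edge_length > self.lobule_wavelength / 10:
            raise ValueError(
                "edge_length too coarse to resolve the lobular folds"
            )
        if inner_skull_radius_mm is not None and self.fold_style == "parallel":
            # exact amplitude bound; the isotropic field's realized maximum
            # is checked against the boundary at generation time instead
            amp = abs(self.folia_amplitude) + abs(self.lobule_amplitude)
            reach = np.linalg.norm(self.center) + self.base_radius + amp
            if reach >= inner_skull_radius_mm:
                raise ValueError(
                    f"recipe reaches {reach:.1f} mm from the head origin, "
                    f"beyond the {inner_skull_radius_mm:g} mm inner skull"
                )


def cerebellum_like(**overrides) -> SurfaceRecipe:
    """Default cerebellum surrogate: deep folia on a nearly closed shell."""
    r = SurfaceRecipe(
        kind="cerebellum-like",
        folia_wavelength=2.0,
        folia_amplitude=1.0,
        lobule_wavelength=20.0,
        lobule_amplitude=3.0,
        cap_center_direction=(0.0, -0.811, -0.586),
        cap_angular_radius=170.0,
        base_radius=25.0,
        edge_length=0.2,
        center=(0.0, -36.0, -26.0),
    )
    return replace(r, **overrides)


def cortex_like(**overrides) -> SurfaceRecipe:
    """Default cerebral-cortex surrogate: disordered isotropic gyral folds.

    Two bands mirror real gyrification: a fine scale at the gyral spacing
    (14 mm wavelength, 6 mm amplitude, i.e. sulcal depths around 12 mm)
    and a coarse lobar undulation (48 mm, 4 mm) that keeps patch normals
    partially coherent at centimeter scales, as the smooth hemispheric
    envelope does.  In the generic two-scale recipe the fine band occupies
    the ``folia`` fields and the coarse band the ``lobule`` fields.
    """
    r = SurfaceRecipe(
        kind="cortex-like",
        folia_wavelength=14.0,
        folia_amplitude=6.0,
        lobule_wavelength=48.0,
        lobule_amplitude=4.0,
        cap_center_direction=(0.0, 0.0, 1.0),
        cap_angular_radius=120.0,
        base_radius=58.0,
        edge_length=1.4,
        center=(0.0, 0.0, 0.0),
        fold_style="isotropic",
    )
    return replace(r, **overrides)


def smoothed_shell(**overrides) -> SurfaceRecipe:
    """Cerebellum-like shell with the folia smoothed away (outer-shell
    segmentation surrogate)."""
    r = cerebellum_like(kind="smoothed-shell", folia_amplitude=0.0,
                        edge_length=1.0)
    return replace(r, **overrides)


PRESETS = {
    "cerebellum-like": cerebellum_like,
    "cortex-like": cortex_like,
    "smoothed-shell": smoothed_shell,
}


def generate_folded_sheet(recipe: SurfaceRecipe,
                          inner_skull_radius_mm: float | None = None
                          ) -> TriangleMesh:
    """Generate the corrugated sheet described by ``recipe``.

    The cap is meshed as a locally subdivided icosphere patch so that every
    edge is at most ``recipe.edge_length``; vertices are then displaced
    radially by the two-scale sinusoid.  Deterministic given the recipe
    (the folia phase is drawn from ``recipe.seed``).
    """
    recipe.validate(inner_skull_radius_mm)
    if recipe.kind == "smoothed-shell" and recipe.folia_amplitude != 0.0:
        raise ValueError("smoothed-shell recipes must have folia_amplitude=0")

    R = recipe.base_radius * 1e-3
    axis = np.asarray(recipe.cap_center_direction, float)
    axis = axis / np.linalg.norm(axis)
    cap = unit_cap_mesh(axis, recipe.cap_angular_radius,
                        max_edge_angle=recipe.edge_length * 1e-3 / R)

    # latitude axis for the corrugation coordinate: a deterministic unit
    # vector orthogonal to the cap axis
    k = int(np.argmin(np.abs(axis)))
    e = np.zeros(3)
    e[k] = 1.0
    e -= axis * (axis @ e)
    e /= np.linalg.norm(e)

    rng = np.random.default_rng(recipe.seed)
    v = cap.vertices  # unit vectors
    lam_l = recipe.lobule_wavelength * 1e-3
    lam_f = recipe.folia_wavelength * 1e-3
    if recipe.fold_style == "parallel":
        # corrugations along one tangential (latitude) axis of the cap
        phase = float(rng.uniform(0.0, 2 * np.pi))
        s = R * np.arcsin(np.clip(v @ e, -1.0, 1.0))  # arc length, meters
        disp = recipe.lobule_amplitude * 1e-3 * np.sin(2 * np.pi * s / lam_l)
        if recipe.folia_amplitude:
            disp = disp + recipe.folia_amplitude * 1e-3 * np.sin(
                2 * np.pi * s / lam_f + phase
            )
    else:
        # disordered isotropic folds: band-limited random field built from
        # plane waves with quasi-uniform directions and seeded phases; RMS
        # displacement per scale is amplitude / sqrt(2), matching the RMS of
        # the parallel sinusoid of equal amplitude
        x = v * R  # positions on the undisplaced sphere, meters
        disp = np.zeros(len(v))
        for lam, amp in ((lam_l, recipe.lobule_amplitude * 1e-3),
                         (lam_f, recipe.folia_amplitude * 1e-3)):
            if amp == 0.0:
                continue
            disp = disp + amp * _isotropic_fold_field(x, lam, rng)
    vertices = np.asarray(recipe.center, float) * 1e-3 + v * (R + disp)[:, None]
    if inner_skull_radius_mm is not None:
        reach = np.linalg.norm(vertices, axis=1).max() * 1e3
        if reach >= inner_skull_radius_mm:
            raise ValueError(
                f"generated surface reaches {reach:.1f} mm from the head "
                f"origin, beyond the {inner_skull_radius_mm:g} mm inner skull"
            )
    mesh = TriangleMesh(vertices, cap.faces)
    mesh.validate()
    return mesh


def _isotropic_fold_field(x: np.ndarray, wavelength_m: float,
                          rng: np.random.Generator, n_waves: int = 24
                          ) -> np.ndarray:
    """Unit-amplitude disordered fold field: sum of ``n_waves`` plane waves
    of the given wavelength with quasi-uniform directions and random phases.
    RMS is 1/sqrt(2) (like a single sinusoid of unit amplitude)."""
    i = np.arange(n_waves) + 0.5
    z = 1.0 - 2.0 * i / n_waves
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z * z)
    dirs = np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)
    phases = rng.uniform(0.0, 2 * np.pi, n_waves)
    args = 2 * np.pi * (x @ dirs.T) / wavelength_m + phases[None, :]
    return np.sin(args).sum(axis=1) / np.sqrt(n_waves)


# -- source space ------------------------------------------------------------


@dataclass
class SourceSpace:
    """Dipole positions/orientations with areas and a patch-adjacency graph.

    ``positions`` are in meters, ``orientations`` unit vectors (fixed,
    along the angle-weighted vertex normals), ``areas`` in m^2 (vertex areas
    of the generating mesh, re-assigned on decimation so total area is
    conserved).  ``kept`` marks sources surviving the inner-skull exclusion;
    excluded sources stay in the arrays (sensitivity maps flag them) but
    never enter signal computations.
    """

    positions: np.ndarray
    orientations: np.ndarray
    areas: np.ndarray
    kept: np.ndarray
    adjacency: sp.csr_matrix
    surface: str = "unnamed"
    #: for decimated spaces: original vertex id of each retained source
    parent_indices: np.ndarray | None = None
    #: for decimated spaces: retained-source index absorbing each original
    #: vertex's area (the geodesic-nearest selected vertex)
    parent_assignment: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.positions)
        if not (len(self.orientations) == len(self.areas) == len(self.kept) == n):
            raise ValueError("inconsistent source-space array lengths")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("orientations must be unit vectors")

    @property
    def n_sources(self) -> int:
        return len(self.positions)

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kept)

    def total_area(self) -> float:
        return float(self.areas.sum())

    def _csr_arrays(self):
        a = self.adjacency
        return a.indptr, a.indices, a.data


def exclude_near_boundary(positions: np.ndarray, boundary: TriangleMesh | float,
                          min_dist_mm: float = 5.0) -> np.ndarray:
    """Mask of sources at least ``min_dist_mm`` from the inner-skull boundary.

    ``boundary`` may be a closed shell mesh or, for the analytic spherical
    head, the inner-skull radius in meters (distance is then computed exactly
    as ``radius - |p|``).  A point outside the boundary raises: it would sit
    outside the brain compartment.
    """
    positions = np.asarray(positions, float)
    if isinstance(boundary, (int, float)):
        radius = float(boundary)
        r = np.linalg.norm(positions, axis=1)
        if np.any(r > radius):
            raise ValueError("source position outside the inner-skull sphere")
        dist = radius - r
    else:
        if boundary.euler_characteristic() != 2:
            raise ValueError("boundary must be a closed shell")
        from .bem import _project_points

        tri_idx, bary = _project_points(boundary, positions)
        tris = boundary.vertices[boundary.faces[tri_idx]]
        closest = np.einsum("pb,pbk->pk", bary, tris)
        delta = positions - closest
        dist = np.linalg.norm(delta, axis=1)
        outward = boundary.face_normals()[tri_idx]
        if np.any(np.einsum("pk,pk->p", delta, outward) > 1e-12):
            raise ValueError("source position outside the inner-skull boundary")
    return dist >= min_dist_mm * 1e-3


def build_source_space(mesh: TriangleMesh, inner_skull_radius_m: float | None,
                       min_dist_mm: float = 5.0, surface: str = "unnamed"
                       ) -> SourceSpace:
    """Source space with one fixed-orientation dipole per mesh vertex."""
    if not mesh.is_connected():
        n_comp, labels = sp.csgraph.connected_components(mesh.vertex_adjacency())
        sizes = np.bincount(labels)
        raise ValueError(
            f"mesh is disconnected: {n_comp} components of sizes {sizes.tolist()}"
        )
    ori = vertex_normals(mesh)
    areas = vertex_areas(mesh)
    if inner_skull_radius_m is None:
        kept = np.ones(mesh.n_vertices, bool)
    else:
        kept = exclude_near_boundary(mesh.vertices, inner_skull_radius_m,
                                     min_dist_mm)
    return SourceSpace(mesh.vertices.copy(), ori, areas, kept,
                       mesh.vertex_adjacency(), surface=surface)


def decimate_source_space(src: SourceSpace, target_count: int) -> SourceSpace:
    """Geodesic farthest-point decimation with area re-assignment.

    Selects ``target_count`` vertices approximately uniformly by geodesic
    spacing (farthest-point sampling with graph shortest-path distances),
    then re-assigns every remaining vertex's area to its geodesically
    nearest selected vertex, conserving total represented area.  The
    decimated adjacency connects selected vertices whose assignment cells
    share an edge in the full graph.
    """
    n = src.n_sources
    if not 1 <= target_count <= n:
        raise ValueError("target_count out of range")
    n_comp, labels = sp.csgraph.connected_components(src.adjacency)
    if n_comp != 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"source space is disconnected: {n_comp} components "
            f"of sizes {sizes.tolist()}"
        )
    if target_count == n:
        return src

    indptr, indices, weights = src._csr_arrays()
    selected, owner, _ = _graph.farthest_point_sample(
        indptr.astype(np.int64), indices.astype(np.int64),
        weights.astype(np.float64), n, int(target_count), 0
    )
    areas = np.bincount(owner, weights=src.areas, minlength=len(selected))

    # cell adjacency: selected vertices whose assignment cells share an edge
    coo = src.adjacency.tocoo()
    ou, ov = owner[coo.row], owner[coo.col]
    m = ou != ov
    pairs = np.unique(np.sort(np.stack([ou[m], ov[m]], 1), axis=1), axis=0)
    pos = src.positions[selected]
    d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
    ns = len(selected)
    adj = sp.coo_matrix(
        (np.r_[d, d], (np.r_[pairs[:, 0], pairs[:, 1]],
                       np.r_[pairs[:, 1], pairs[:, 0]])),
        shape=(ns, ns),
    ).tocsr()

    return SourceSpace(
        positions=pos.copy(),
        orientations=src.orientations[selected].copy(),
        areas=areas,
        kept=src.kept[selected].copy(),
        adjacency=adj,
        surface=src.surface,
        parent_indices=selected.copy(),
        parent_assignment=owner.copy(),
    )


def grow_patch(src: SourceSpace, seed_vertex: int, target_area_m2: float):
    """Grow a coherent patch by ring-wise breadth-first accretion.

    Whole rings of graph neighbors (restricted to kept sources) are added
    in graph-distance order, ties within a ring broken by ascending vertex
    index, until the summed vertex area first reaches ``target_area_m2``.

    Returns ``(members, realized_area_m2)``.
    """
    if not src.kept[seed_vertex]:
        raise ValueError(f"seed vertex {seed_vertex} was excluded")
    if target_area_m2 < 0:
        raise ValueError("target_area must be >= 0")
    total = float(src.areas[src.kept].sum())
    if target_area_m2 > total:
        warnings.warn(
            f"target area {target_area_m2:.3e} m^2 exceeds the surface's "
            f"kept area {total:.3e} m^2; returning all kept sources",
            stacklevel=2,
        )
    indptr, indices, _ = src._csr_arrays()
    members, nm, area = _graph.grow_patch_rings(
        indptr.astype(np.int64), indices.astype(np.int64),
        src.kept.astype(np.uint8), src.areas.astype(np.float64),
        int(seed_vertex), float(target_area_m2),
    )
    return members[:nm].copy(), float(area)


def patch_radius_to_area(radius_mm: float) -> float:
    """Flat-disc equivalent target area (m^2) for a nominal patch radius."""
    return np.pi * (radius_mm * 1e-3) ** 2
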