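"""Three-compartment boundary-element method with linear collocation.

Solves the surface-potential integral equation of the piecewise-homogeneous
conductor (Geselowitz): for an observation point on interface ``l``,

    (sigma_l_in + sigma_l_out)/2 phi(x) =
        sigma_src phi_inf(x)
        + (1/4 pi) sum_k (sigma_k_in - sigma_k_out)
                   PV int_{S_k} phi(y) dOmega_x(y)

with ``dOmega_x(y) = ((y - x) . n_hat(y)) / |y - x|^3 dS``.  The potential is
linear over each triangle and collocated at vertices; the per-triangle,
per-vertex solid-angle weights are the analytically integrated elements of
de Munck (1992).  The singular system is deflated (the potential's free
constant), and for the realistic skull/brain conductivity ratio the
isolated-skull approach of Haemaelaeinen & Sarvas (1989) is applied (on by
default; essential for accuracy when sigma_skull << sigma_brain).

MEG uses the Geselowitz field formula: the primary (Biot-Savart) dipole
field plus the volume-current boundary integral of the solved surface
potentials (one-point centroid quadrature per triangle).

Surfaces are ordered innermost first: brain, skull, scalp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meshes import TriangleMesh
from .sensors import (
    ELECTRODE,
    GRADIOMETER_X,
    GRADIOMETER_Y,
    MAGNETOMETER,
    SensorArray,
    tangent_axes,
)

MU0_OVER_4PI = 1e-7

_ISA_RATIO_LIMIT = 0.1  # apply isolated-skull handling below this sigma ratio


def _lin_collocation_weights(obs: np.ndarray, tri: np.ndarray,
                             tri_n: np.ndarray, tri_area: float) -> np.ndarray:
    """Analytic linear-collocation weights omega_i for one triangle.

    ``omega[p, i]`` is the principal-value integral of the hat function of
    triangle vertex ``i`` against the solid-angle kernel, seen from
    observation points ``obs`` (shape (p, 3)).  The three weights sum to the
    triangle's total solid angle.  Analytically integrated elements after
    de Munck (1992).
    """
    v = tri[None, :, :] - obs[:, None, :]  # (p,3verts,3)
    l = np.linalg.norm(v, axis=2)  # (p,3)
    v1, v2, v3 = v[:, 0], v[:, 1], v[:, 2]
    l1, l2, l3 = l[:, 0], l[:, 1], l[:, 2]

    triple = np.einsum("pk,pk->p", np.cross(v1, v2), v3)
    ss = (l1 * l2 * l3 + np.einsum("pk,pk->p", v1, v2) * l3
          + np.einsum("pk,pk->p", v1, v3) * l2
          + np.einsum("pk,pk->p", v2, v3) * l1)
    solid = 2.0 * np.arctan2(triple, ss)  # total solid angle (signed)

    # degenerate observation points (on the triangle plane through an edge)
    bad = np.abs(np.arctan2(triple, ss)) < np.pi / 1e6
    l1s, l2s, l3s = (np.where(bad, 1.0, l1), np.where(bad, 1.0, l2),
                     np.where(bad, 1.0, l3))

    def beta(va, la, vb, lb):
        e = vb - va
        elen = np.linalg.norm(e, axis=1)
        e = e / elen[:, None]
        num = la + np.einsum("pk,pk->p", va, e)
        den = lb + np.einsum("pk,pk->p", vb, e)
        return np.log(num / den) / elen

    b12 = beta(v1, l1s, v2, l2s)
    b23 = beta(v2, l2s, v3, l3s)
    b31 = beta(v3, l3s, v1, l1s)
    vec = ((b31 - b12)[:, None] * v1 + (b12 - b23)[:, None] * v2
           + (b23 - b31)[:, None] * v3)

    area2 = 2.0 * tri_area
    omega = np.empty((len(obs), 3))
    pairs = ((v2, v3), (v3, v1), (v1, v2))  # (next, prev) per vertex
    diffs = (v3 - v2, v1 - v3, v2 - v1)
    for k, ((vn, vp), dv) in enumerate(zip(pairs, diffs)):
        zd = np.einsum("pk,k->p", np.cross(vn, vp), tri_n)
        omega[:, k] = (area2 * zd * solid
                       - triple * np.einsum("pk,pk->p", dv, vec)) / (area2 ** 2)
    omega[bad] = 0.0
    return omega


def _project_points(mesh: TriangleMesh, points: np.ndarray):
    """Closest-triangle projection with barycentric weights.

    Candidate faces are those incident to the Euclidean-nearest vertex,
    which is exact for points close to a well-shaped mesh (electrodes on
    the scalp boundary).  Returns ``(tri_idx, barycentric)``.
    """
    from scipy.spatial import cKDTree
    import trimesh.triangles as tt

    tree = cKDTree(mesh.vertices)
    _, nearest = tree.query(points)
    # incident faces per vertex
    tri_of = [[] for _ in range(mesh.n_vertices)]
    for t, f in enumerate(mesh.faces):
        for v in f:
            tri_of[v].append(t)
    tri_idx = np.empty(len(points), dtype=np.int64)
    bary = np.empty((len(points), 3))
    tris = mesh.vertices[mesh.faces]
    for i, p in enumerate(points):
        cand = tri_of[nearest[i]]
        cp = tt.closest_point(tris[cand], np.tile(p, (len(cand), 1)))
        d = np.linalg.norm(cp - p, axis=1)
        k = int(np.argmin(d))
        tri_idx[i] = cand[k]
        b = tt.points_to_barycentric(tris[[cand[k]]], cp[[k]])[0]
        bary[i] = np.clip(b, 0.0, 1.0)
        bary[i] /= bary[i].sum()
    return tri_idx, bary


def _surface_data(mesh: TriangleMesh):
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area = 0.5 * np.linalg.norm(cross, axis=1)
    nrm = cross / (2.0 * area)[:, None]
    return tri, nrm, area


def _pot_coeff_block(obs: np.ndarray, mesh: TriangleMesh,
                     skip_own: bool = False) -> np.ndarray:
    """PV solid-angle matrix: obs points x vertices of ``mesh``.

    With ``skip_own`` (observation points are the mesh's own vertices),
    triangles incident to an observation vertex are excluded there and the
    row deficit relative to the closed-surface principal value 2 pi is
    restored: half to the vertex itself, the rest spread over the incident
    triangles' other vertices.
    """
    tri, nrm, area = _surface_data(mesh)
    out = np.zeros((len(obs), mesh.n_vertices))
    for t in range(mesh.n_faces):
        om = _lin_collocation_weights(obs, tri[t], nrm[t], area[t])
        if skip_own:
            om[mesh.faces[t], :] = 0.0
        np.add.at(out, (slice(None), mesh.faces[t]), om)
    if skip_own:
        miss = 2.0 * np.pi - out.sum(axis=1)
        for j in range(mesh.n_vertices):
            out[j, j] += miss[j] / 2.0
        # spread the rest over the incident triangles' opposite vertices
        inc_count = np.bincount(mesh.faces.ravel(), minlength=mesh.n_vertices)
        rest = miss / 2.0
        for t in range(mesh.n_faces):
            i0, i1, i2 = mesh.faces[t]
            for a, b, c in ((i0, i1, i2), (i1, i2, i0), (i2, i0, i1)):
                out[a, b] += rest[a] / (2.0 * inc_count[a])
                out[a, c] += rest[a] / (2.0 * inc_count[a])
    return out


@dataclass
class BemModel:
    """Assembled linear-collocation BEM for nested closed boundary meshes.

    Parameters
    ----------
    surfaces : list of TriangleMesh
        Closed, non-intersecting boundaries ordered innermost first
        (brain, skull, scalp for the three-compartment head).
    conductivities : list of float
        Compartment conductivities (S/m), innermost first; outside the last
        surface is non-conducting.
    isolated_skull : bool
        Apply the isolated-skull approach when
        ``sigma_skull / sigma_brain`` is small (default True).
    """

    surfaces: list
    conductivities: list
    isolated_skull: bool = True

    def __post_init__(self):
        if len(self.surfaces) != len(self.conductivities):
            raise ValueError("one conductivity per surface required")
        for s in self.surfaces:
            s.validate()
            if s.euler_characteristic() != 2:
                raise ValueError("BEM boundaries must be closed shells")
        self._assemble()

    # conductivity bookkeeping: sigma_in[k] inside surface k, sigma_out[k]
    # outside (0 beyond the scalp)
    def _sigmas(self):
        s = list(self.conductivities)
        return np.array(s), np.array(s[1:] + [0.0])

    def _assemble(self):
        surfs = self.surfaces
        nps = [s.n_vertices for s in surfs]
        off = np.concatenate([[0], np.cumsum(nps)])
        ntot = off[-1]
        s_in, s_out = self._sigmas()

        omega = np.zeros((ntot, ntot))
        for l, sl in enumerate(surfs):
            for k, sk in enumerate(surfs):
                omega[off[l]:off[l + 1], off[k]:off[k + 1]] = _pot_coeff_block(
                    sl.vertices, sk, skip_own=(l == k)
                )

        gamma = np.zeros((len(surfs), len(surfs)))
        for l in range(len(surfs)):
            for k in range(len(surfs)):
                gamma[l, k] = (s_in[k] - s_out[k]) / (s_in[l] + s_out[l])

        # M = I - Gamma (x) Omega / (2 pi), deflated by the constant mode
        M = np.eye(ntot) + 1.0 / ntot
        for l in range(len(surfs)):
            for k in range(len(surfs)):
                M[off[l]:off[l + 1], off[k]:off[k + 1]] -= (
                    gamma[l, k] / (2.0 * np.pi)
                ) * omega[off[l]:off[l + 1], off[k]:off[k + 1]]
        cond = np.linalg.cond(M)
        if not np.isfinite(cond) or cond > 1e8:
            raise RuntimeError(
                f"collocation matrix ill-conditioned (cond={cond:.2e}); "
                "check boundary meshes for intersections or degeneracies"
            )
        solution = np.linalg.inv(M)

        if (self.isolated_skull and len(surfs) == 3
                and s_in[1] / s_in[0] < _ISA_RATIO_LIMIT):
            # isolated-skull approach: solve the brain compartment alone
            # (unit gamma), then fold the correction into the solution
            # operator (Haemaelaeinen & Sarvas 1989)
            n0 = nps[0]
            om0 = omega[:n0, :n0]
            M0 = np.eye(n0) + 1.0 / n0 - om0 / (2.0 * np.pi)
            ip = np.linalg.inv(M0)
            ip_mult = s_in[1] / s_in[0]  # sigma_skull / sigma_brain
            sub = solution[:, :n0]
            sub -= 2.0 * (sub @ ip)
            solution[:n0, :n0] += ((1.0 + ip_mult) / ip_mult) * ip
            solution *= ip_mult

        self._solution = solution
        self._offsets = off
        self._source_mult = 2.0 / (s_in + s_out)
        self._field_mult = s_in - s_out

    # -- potentials ----------------------------------------------------------

    def surface_potentials(self, dip_pos: np.ndarray, dip_mom: np.ndarray
                           ) -> np.ndarray:
        """Solved potentials at all boundary vertices, shape (ntot, ndip).

        The mean over the scalp surface (area-weighted) is removed, matching
        the zero-mean convention of the analytic series solution.
        """
        dip_pos = np.atleast_2d(dip_pos)
        dip_mom = np.atleast_2d(dip_mom)
        off = self._offsets
        ntot = off[-1]
        v0 = np.empty((ntot, len(dip_pos)))
        for l, surf in enumerate(self.surfaces):
            d = surf.vertices[:, None, :] - dip_pos[None, :, :]
            dn = np.linalg.norm(d, axis=2)
            pot_inf = np.einsum("vnk,nk->vn", d, dip_mom) / dn ** 3
            v0[off[l]:off[l + 1]] = (
                self._source_mult[l] / (4.0 * np.pi)
            ) * pot_inf
        phi = self._solution @ v0

        from .meshes import vertex_areas

        scalp = self.surfaces[-1]
        w = vertex_areas(scalp)
        block = phi[off[-2]:off[-1]]
        phi -= (w @ block / w.sum())[None, :]
        return phi

    def eeg_potentials(self, dip_pos, dip_mom, electrodes: np.ndarray
                       ) -> np.ndarray:
        """Potentials (V) at electrode positions, shape (e, ndip).

        Electrodes are mapped to the scalp mesh by closest-point projection
        and interpolated with barycentric weights.
        """
        phi = self.surface_potentials(dip_pos, dip_mom)
        off = self._offsets
        scalp_phi = phi[off[-2]:off[-1]]
        scalp = self.surfaces[-1]
        tri_idx, bary = _project_points(scalp, np.atleast_2d(electrodes))
        out = np.einsum("eb,ebn->en", bary, scalp_phi[scalp.faces[tri_idx]])
        return out

    # -- magnetic field ------------------------------------------------------

    def meg_field(self, dip_pos, dip_mom, points: np.ndarray) -> np.ndarray:
        """Magnetic field (T) at exterior points, shape (p, ndip, 3).

        Primary dipole field plus the Geselowitz volume-current boundary
        integral of the solved surface potentials (centroid quadrature).
        """
        dip_pos = np.atleast_2d(dip_pos)
        dip_mom = np.atleast_2d(dip_mom)
        points = np.atleast_2d(points)
        phi = self.surface_potentials(dip_pos, dip_mom)
        off = self._offsets

        d = points[:, None, :] - dip_pos[None, :, :]
        dn = np.linalg.norm(d, axis=2)
        B = MU0_OVER_4PI * np.cross(
            np.broadcast_to(dip_mom[None], d.shape), d
        ) / (dn ** 3)[:, :, None]

        for l, surf in enumerate(self.surfaces):
            mult = self._field_mult[l]
            if mult == 0.0:
                continue
            tri, nrm, area = _surface_data(surf)
            cent = tri.mean(axis=1)  # (t,3)
            phi_c = phi[off[l]:off[l + 1]][surf.faces].mean(axis=1)  # (t,ndip)
            rc = points[:, None, :] - cent[None, :, :]  # (p,t,3)
            rcn3 = np.linalg.norm(rc, axis=2) ** 3
            kern = np.cross(np.broadcast_to(nrm[None], rc.shape), rc)
            kern /= rcn3[:, :, None]  # (p,t,3)
            kern *= area[None, :, None]
            B -= MU0_OVER_4PI * mult * np.einsum("ptk,tn->pnk", kern, phi_c)
        return B

    # -- gain assembly -------------------------------------------------------

    def gain(self, positions, orientations, sensors: SensorArray,
             chunk: int = 512) -> np.ndarray:
        """Unit-dipole gain for all channels of ``sensors``."""
        n = len(positions)
        out = np.empty((sensors.n_channels, n))
        types = sensors.types.astype(str)
        is_el = types == ELECTRODE
        meg = ~is_el
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            pos, mom = positions[lo:hi], orientations[lo:hi]
            if np.any(is_el):
                out[np.flatnonzero(is_el), lo:hi] = self.eeg_potentials(
                    pos, mom, sensors.positions[is_el])
            if np.any(meg):
                mpos = sensors.positions[meg]
                mori = sensors.orientations[meg]
                mtypes = types[meg]
                mbase = sensors.baselines_mm[meg]
                u = mpos / np.linalg.norm(mpos, axis=1, keepdims=True)
                t1, t2 = tangent_axes(u)
                vals = np.empty((len(mpos), hi - lo))
                mm = mtypes == MAGNETOMETER
                if np.any(mm):
                    B = self.meg_field(pos, mom, mpos[mm])
                    vals[mm] = np.einsum("mnk,mk->mn", B, mori[mm])
                for sel, axes in ((mtypes == GRADIOMETER_X, t1),
                                  (mtypes == GRADIOMETER_Y, t2)):
                    if not np.any(sel):
                        continue
                    dlt = (mbase[sel] * 1e-3 / 2.0)[:, None]
                    Bp = self.meg_field(pos, mom, mpos[sel] + dlt * axes[sel])
                    Bm = self.meg_field(pos, mom, mpos[sel] - dlt * axes[sel])
                    comp = np.einsum("mnk,mk->mn", Bp - Bm, mori[sel])
                    vals[sel] = comp / (2.0 * dlt)
                out[np.flatnonzero(meg), lo:hi] = vals
        return out
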