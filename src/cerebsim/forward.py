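"""Forward models: current-dipole fields at M/EEG sensors.

Two engines are provided:

``sphere_analytic`` (default)
    The closed-form magnetic field of a current dipole in a spherically
    symmetric conductor (Sarvas' formula) for MEG, and the Legendre-series
    potential of a dipole in concentric three-shell spheres for EEG.  Exact,
    fast and deterministic; also the oracle for the BEM.
``bem_collocation``
    Three-compartment boundary-element method with linear collocation
    (:mod:`cerebsim.bem`), for non-spherical compartment boundaries.

Everything is SI: positions m, dipole moments A*m, magnetometer outputs T,
planar-gradiometer outputs T/m, potentials V.  Gain-matrix columns are the
forward solutions of unit (1 A*m) dipoles; physiological scaling is applied
downstream by the cancelation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import SourceSpace
from .sensors import (
    ELECTRODE,
    GRADIOMETER_X,
    GRADIOMETER_Y,
    MAGNETOMETER,
    HeadModel,
    SensorArray,
    tangent_axes,
)

MU0_OVER_4PI = 1e-7  # T*m/A


# -- MEG: spherically symmetric conductor ------------------------------------


def meg_field_sphere(dip_pos: np.ndarray, dip_mom: np.ndarray,
                     points: np.ndarray, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Magnetic field (T) of current dipoles in a spherical conductor.

    Sarvas' closed form: with ``a = r - r0``, ``F = a (r a + r^2 - r0.r)``,

        B(r) = (mu0 / 4 pi F^2) (F Q x r0 - (Q x r0 . r) grad F)

    The volume-current contribution is built in; a radial dipole is exactly
    silent, and a dipole at the center produces no field.  Shapes:
    ``dip_pos``/``dip_mom`` (n, 3), ``points`` (m, 3); returns (m, n, 3).
    """
    c = np.asarray(center, float)
    r0 = np.atleast_2d(dip_pos) - c  # (n,3)
    q = np.atleast_2d(dip_mom)
    r = np.atleast_2d(points) - c  # (m,3)

    rn = np.linalg.norm(r, axis=1)  # (m,)
    r0n = np.linalg.norm(r0, axis=1)  # (n,)
    if np.any(rn[:, None] <= r0n[None, :]):
        raise ValueError("field point inside the source radius")

    a = r[:, None, :] - r0[None, :, :]  # (m,n,3)
    an = np.linalg.norm(a, axis=2)  # (m,n)
    rdotr0 = r @ r0.T
    r2 = (rn ** 2)[:, None]
    F = an * (rn[:, None] * an + r2 - rdotr0)
    adotr = np.einsum("mnk,mk->mn", a, r)
    cF = an ** 2 / rn[:, None] + adotr / an + 2.0 * an + 2.0 * rn[:, None]
    cF0 = an + 2.0 * rn[:, None] + adotr / an
    gradF = cF[:, :, None] * r[:, None, :] - cF0[:, :, None] * r0[None, :, :]

    qxr0 = np.cross(q, r0)  # (n,3)
    qxr0_dot_r = np.einsum("nk,mk->mn", qxr0, r)
    B = F[:, :, None] * qxr0[None, :, :] - qxr0_dot_r[:, :, None] * gradF
    B *= MU0_OVER_4PI / (F ** 2)[:, :, None]
    return B


# -- EEG: concentric three-shell spheres -------------------------------------


def _shell_transfer(head: HeadModel, n_terms: int) -> np.ndarray:
    """Per-degree outer-surface transfer factors ``w[n]``.

    In each shell the degree-``n`` potential is ``A rho^n + B rho^-(n+1)``;
    the source contributes a unit ``rho^-(n+1)`` term in the innermost
    shell.  Continuity of potential and radial current density at the two
    interfaces plus the insulating outer boundary give a 5x5 linear system
    per degree; ``w[n]`` is the outer-surface potential per unit source
    coefficient.  For equal conductivities this reduces to the homogeneous
    sphere's ``(2n+1)/n / r3^(n+1)``.
    """
    r1, r2, r3 = head.radii_m()
    s1, s2, s3 = head.conductivities
    w = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        # unknowns: A1, A2, B2, A3, B3 (source coefficient fixed at 1)
        M = np.array([
            [r1 ** n, -(r1 ** n), -(r1 ** -(n + 1)), 0.0, 0.0],
            [s1 * n * r1 ** (n - 1), -s2 * n * r1 ** (n - 1),
             s2 * (n + 1) * r1 ** -(n + 2), 0.0, 0.0],
            [0.0, r2 ** n, r2 ** -(n + 1), -(r2 ** n), -(r2 ** -(n + 1))],
            [0.0, s2 * n * r2 ** (n - 1), -s2 * (n + 1) * r2 ** -(n + 2),
             -s3 * n * r2 ** (n - 1), s3 * (n + 1) * r2 ** -(n + 2)],
            [0.0, 0.0, 0.0, n * r3 ** (n - 1), -(n + 1) * r3 ** -(n + 2)],
        ])
        rhs = np.array([
            -(r1 ** -(n + 1)),
            s1 * (n + 1) * r1 ** -(n + 2),
            0.0, 0.0, 0.0,
        ])
        A1, A2, B2, A3, B3 = np.linalg.solve(M, rhs)
        w[n] = A3 * r3 ** n + B3 * r3 ** -(n + 1)
    return w


def eeg_potential_spheres(dip_pos: np.ndarray, dip_mom: np.ndarray,
                          electrodes: np.ndarray, head: HeadModel,
                          center=(0.0, 0.0, 0.0), tol: float = 1e-8,
                          max_terms: int = 400) -> np.ndarray:
    """Electrode potentials (V) of dipoles in the concentric three-shell head.

    Frame-free Legendre series: with the dipole at radius ``b`` split into
    radial (``q_r``) and tangential (``q_t``) parts and ``u`` the cosine of
    the angle between dipole and electrode directions,

        V = sum_n  w_n / (4 pi sigma_brain) * b^(n-1)
                   * [ n q_r P_n(u) + P_n'(u) (q_t . e_hat) ]

    truncated once the geometric tail bound drops below ``tol`` relative.
    Shapes: ``dip_pos``/``dip_mom`` (n, 3), ``electrodes`` (e, 3) on the
    scalp sphere; returns (e, n).
    """
    c = np.asarray(center, float)
    r0 = np.atleast_2d(dip_pos) - c
    q = np.atleast_2d(dip_mom)
    re = np.atleast_2d(electrodes) - c
    r1, r2, r3 = head.radii_m()
    s1 = head.conductivities[0]

    ren = np.linalg.norm(re, axis=1)
    if np.any(np.abs(ren - r3) > 1e-6 * r3):
        raise ValueError("electrodes must lie on the scalp sphere")
    re_hat = re / ren[:, None]

    b = np.linalg.norm(r0, axis=1)
    if np.any(b >= r1):
        raise ValueError("dipole outside the innermost shell")

    bmax = float(b.max())
    if bmax == 0.0:
        n_terms = 10
    else:
        n_terms = max(10, int(np.ceil(np.log(tol) / np.log(bmax / r3))) + 10)
    if n_terms > max_terms:
        achieved = (bmax / r3) ** max_terms
        raise ValueError(
            f"series would need ~{n_terms} terms to reach tol={tol:g} "
            f"(achievable ~{achieved:.1e} with {max_terms}); dipole too "
            "close to the outer boundary"
        )
    w = _shell_transfer(head, n_terms)

    safe_b = np.where(b > 0, b, 1.0)
    r0_hat = np.where((b > 0)[:, None], r0 / safe_b[:, None],
                      np.array([0.0, 0.0, 1.0]))
    q_r = np.einsum("nk,nk->n", q, r0_hat)
    q_t = q - q_r[:, None] * r0_hat

    u = re_hat @ r0_hat.T  # (e,n)
    qt_dot_e = re_hat @ q_t.T  # (e,n)

    # P_n and P_n' by recurrence
    p_prev = np.ones_like(u)   # P_0
    p_cur = u.copy()           # P_1
    dp_prev = np.zeros_like(u)  # P_0'
    dp_cur = np.ones_like(u)   # P_1'
    out = np.zeros_like(u)
    bpow = np.ones_like(b)     # b^(n-1) at n=1
    for n in range(1, n_terms + 1):
        coef = w[n] / (4.0 * np.pi * s1)
        out += coef * ((n * q_r * bpow)[None, :] * p_cur
                       + bpow[None, :] * qt_dot_e * dp_cur)
        bpow = bpow * b
        p_next = ((2 * n + 1) * u * p_cur - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
    return out


# -- engines and gain matrices ----------------------------------------------


@dataclass
class ForwardEngine:
    """Forward-solution engine selector.

    ``method`` is ``"sphere_analytic"`` or ``"bem_collocation"``; the BEM
    path needs boundary meshes (``bem_subdivisions`` icosphere levels are
    generated from the head model when none are supplied).
    """

    head: HeadModel = field(default_factory=HeadModel)
    method: str = "sphere_analytic"
    sphere_center: tuple = (0.0, 0.0, 0.0)
    bem_subdivisions: int = 3
    isolated_skull: bool = True
    _bem_model: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.method not in ("sphere_analytic", "bem_collocation"):
            raise ValueError(f"unknown forward method {self.method!r}")

    def _bem(self):
        if self._bem_model is None:
            from .bem import BemModel

            self._bem_model = BemModel(
                self.head.boundary_meshes(self.bem_subdivisions),
                list(self.head.conductivities),
                isolated_skull=self.isolated_skull,
            )
        return self._bem_model


@dataclass
class GainMatrix:
    """M x N forward matrix of unit-dipole signals.

    Row ``i`` is a channel (type and unit in ``channel_types`` /
    ``channel_units``), column ``j`` the forward solution of a unit
    (1 A*m) dipole at source ``j``.  EEG rows are stored unreferenced;
    referencing is an explicit downstream operator.
    """

    values: np.ndarray
    channel_names: list
    channel_types: np.ndarray
    channel_units: np.ndarray
    source_indices: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("gain matrix contains non-finite entries")

    @property
    def shape(self):
        return self.values.shape

    def modality_rows(self, modality: str) -> np.ndarray:
        from .sensors import MODALITIES

        return np.isin(self.channel_types.astype(str), MODALITIES[modality])

    def modality_values(self, modality: str) -> np.ndarray:
        return self.values[self.modality_rows(modality)]

    def save(self, path) -> None:
        """NPZ container with CSV-mirrored channel/source metadata."""
        np.savez_compressed(
            path,
            values=self.values,
            channel_names=np.array(self.channel_names, dtype=str),
            channel_types=self.channel_types.astype(str),
            channel_units=self.channel_units.astype(str),
            source_indices=self.source_indices,
        )
        meta = pd.DataFrame({
            "channel_name": self.channel_names,
            "type": self.channel_types.astype(str),
            "units": self.channel_units.astype(str),
        })
        meta.to_csv(str(path) + ".channels.csv", index=False)

    @classmethod
    def load(cls, path) -> "GainMatrix":
        z = np.load(path)
        return cls(
            z["values"],
            [str(n) for n in z["channel_names"]],
            z["channel_types"].astype(object),
            z["channel_units"].astype(object),
            z["source_indices"],
        )


def average_reference(values: np.ndarray) -> np.ndarray:
    """Subtract the mean over channels (rows) from each column."""
    return values - values.mean(axis=0, keepdims=True)


def _sphere_gain_block(positions, orientations, sensors: SensorArray,
                       engine: ForwardEngine, chunk: int = 8192) -> np.ndarray:
    """Unit-dipole gain for all channels of ``sensors`` (sphere engine)."""
    n = len(positions)
    out = np.empty((sensors.n_channels, n))
    center = np.asarray(engine.sphere_center, float)

    types = sensors.types.astype(str)
    is_mag = types == MAGNETOMETER
    is_gx = types == GRADIOMETER_X
    is_gy = types == GRADIOMETER_Y
    is_el = types == ELECTRODE
    meg = is_mag | is_gx | is_gy

    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        pos = positions[lo:hi]
        mom = orientations[lo:hi]
        if np.any(meg):
            mpos = sensors.positions[meg]
            mori = sensors.orientations[meg]
            mtypes = types[meg]
            mbase = sensors.baselines_mm[meg]
            u = mpos - center
            u = u / np.linalg.norm(u, axis=1, keepdims=True)
            t1, t2 = tangent_axes(u)
            vals = np.empty((len(mpos), hi - lo))
            mm = mtypes == MAGNETOMETER
            if np.any(mm):
                B = meg_field_sphere(pos, mom, mpos[mm], center)
                vals[mm] = np.einsum("mnk,mk->mn", B, mori[mm])
            for sel, axes in ((mtypes == GRADIOMETER_X, t1),
                              (mtypes == GRADIOMETER_Y, t2)):
                if not np.any(sel):
                    continue
                d = (mbase[sel] * 1e-3 / 2.0)[:, None]
                p_plus = mpos[sel] + d * axes[sel]
                p_minus = mpos[sel] - d * axes[sel]
                Bp = meg_field_sphere(pos, mom, p_plus, center)
                Bm = meg_field_sphere(pos, mom, p_minus, center)
                comp = np.einsum("mnk,mk->mn", Bp - Bm, mori[sel])
                vals[sel] = comp / (2.0 * d)
            out[np.flatnonzero(meg), lo:hi] = vals
        if np.any(is_el):
            v = eeg_potential_spheres(pos, mom, sensors.positions[is_el],
                                      engine.head, center)
            out[np.flatnonzero(is_el), lo:hi] = v
    return out


def compute_gain(source_space: SourceSpace, sensors: SensorArray,
                 engine: ForwardEngine | None = None,
                 kept_only: bool = True) -> GainMatrix:
    """Forward matrix with one column per (kept) source vertex.

    Columns are unit-moment (1 A*m) forward solutions; rows follow the
    sensor array's channel order.  EEG rows are unreferenced.
    """
    engine = engine or ForwardEngine()
    idx = source_space.kept_indices if kept_only else np.arange(
        source_space.n_sources)
    if len(idx) == 0:
        raise ValueError("source space is empty after exclusion")
    pos = source_space.positions[idx]
    ori = source_space.orientations[idx]
    if engine.method == "sphere_analytic":
        values = _sphere_gain_block(pos, ori, sensors, engine)
    else:
        values = engine._bem().gain(pos, ori, sensors)
    return GainMatrix(values, list(sensors.names), sensors.types,
                      sensors.units(), idx)
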