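"""Signal-cancelation statistics: net/absolute signal, conservation factor,
and physiologically scaled norms.

For a set of ``n`` simultaneously active unit current dipoles with forward
columns ``G[:, j]`` (single channel type):

* net signal       ``A = || sum_j G[:, j] ||_2``
* absolute signal  ``B = sum_j || G[:, j] ||_2``
* conservation factor ``C = A / B`` (in [0, 1]; the cancelation index is
  ``1 - C``)

The physiological norms rescale each dipole to carry moment
``a_n * q0 / n`` so the activated patch of area ``a_n`` has a uniform
current-dipole density of q0 = 1 nAm/mm^2 (the invariant density observed
across cortical structures):

* ``alpha = A * a_n * q0 / n``,  ``beta = B * a_n * q0 / n``,  so ``C = alpha/beta``.

``alpha`` and ``beta`` are invariant to source-grid density; all norms are
computed per modality (magnetometers, gradiometers, EEG) and never pooled
across channel types.  EEG columns are average-referenced before norms by
default (a flag disables this).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import GainMatrix, average_reference

#: current-dipole surface density, SI: 1e-9 A*m / mm^2 = 1e-3 A/m
Q0_SI = 1e-3
#: sensitivity-map dipole moment: 100 nAm
SENSITIVITY_MOMENT_AM = 100e-9


@dataclass
class PhysiologicalConstants:
    """Scale factors tying unit-dipole math to physiological currents."""

    q0_am_per_mm2: float = 1e-9  # A*m per mm^2
    sensitivity_moment_nam: float = 100.0

    @property
    def q0_si(self) -> float:  # A/m
        return self.q0_am_per_mm2 * 1e6

    def __post_init__(self):
        if self.q0_am_per_mm2 != 1e-9 or self.sensitivity_moment_nam != 100.0:
            import logging

            logging.getLogger(__name__).warning(
                "overriding physiological constants: q0=%g Am/mm^2, "
                "moment=%g nAm", self.q0_am_per_mm2,
                self.sensitivity_moment_nam,
            )


@dataclass
class CancelationResult:
    """One activation's cancelation summary (single modality)."""

    n: int
    a_n_mm2: float
    A: float
    B: float
    C: float
    alpha: float
    beta: float
    modality: str = ""

    @property
    def cancelation_index(self) -> float:
        return 1.0 - self.C


def _modality_block(G: GainMatrix | np.ndarray, modality: str | None,
                    reference_eeg: bool) -> np.ndarray:
    if isinstance(G, np.ndarray):
        return G
    if modality is None:
        types = set(G.channel_types.astype(str))
        if len(types) > 1:
            raise ValueError(
                f"gain matrix mixes channel types {sorted(types)}; "
                "pass modality= to select one"
            )
        block = G.values
        is_eeg = types == {"electrode"}
    else:
        block = G.modality_values(modality)
        is_eeg = modality == "eeg"
    if is_eeg and reference_eeg:
        block = average_reference(block)
    return block


def net_signal(G, active, modality: str | None = None,
               reference_eeg: bool = True) -> float:
    """``A``: Euclidean channel norm of the summed active columns."""
    block = _modality_block(G, modality, reference_eeg)
    active = np.asarray(active)
    if active.size == 0:
        raise ValueError("active set is empty")
    return float(np.linalg.norm(block[:, active].sum(axis=1)))


def absolute_signal(G, active, modality: str | None = None,
                    reference_eeg: bool = True) -> float:
    """``B``: sum of the active columns' Euclidean channel norms."""
    block = _modality_block(G, modality, reference_eeg)
    active = np.asarray(active)
    if active.size == 0:
        raise ValueError("active set is empty")
    return float(np.linalg.norm(block[:, active], axis=0).sum())


def conservation_factor(A: float, B: float) -> float:
    """``C = A / B`` (0: complete cancelation, 1: none)."""
    if B < 0:
        raise ValueError("absolute signal must be >= 0")
    if B == 0:
        raise ValueError("no signal at all (B = 0); C undefined")
    return A / B


def cancelation_index(A: float, B: float) -> float:
    """``I_c = 1 - C``."""
    return 1.0 - conservation_factor(A, B)


def physiological_norms(A: float, B: float, n: int, a_n_mm2: float,
                        constants: PhysiologicalConstants | None = None):
    """``(alpha, beta)``: norms rescaled to 1 nAm/mm^2 patch density.

    Each of the ``n`` dipoles carries moment ``a_n * q0 / n`` (A*m with
    ``a_n`` in mm^2), so ``alpha/beta`` still equals ``A/B``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if a_n_mm2 <= 0:
        raise ValueError("activated area must be positive")
    constants = constants or PhysiologicalConstants()
    scale = a_n_mm2 * constants.q0_am_per_mm2 / n
    return A * scale, B * scale


def evaluate_activation(G, active, a_n_mm2: float, modality: str,
                        reference_eeg: bool = True,
                        constants: PhysiologicalConstants | None = None
                        ) -> CancelationResult:
    """All cancelation statistics for one active dipole set."""
    block = _modality_block(G, modality, reference_eeg)
    active = np.asarray(active)
    A = float(np.linalg.norm(block[:, active].sum(axis=1)))
    B = float(np.linalg.norm(block[:, active], axis=0).sum())
    C = conservation_factor(A, B)
    alpha, beta = physiological_norms(A, B, len(active), a_n_mm2, constants)
    return CancelationResult(len(active), a_n_mm2, A, B, C, alpha, beta,
                             modality)


@dataclass
class NormalizedCurve:
    """Cerebellar cancelation curves normalized to the cortical mean.

    Per radius grid point ``r`` (mm) the summaries are ratios of condition
    means: ``C~ = mean C_cb / mean C_ctx`` and ``beta~ = mean beta_cb /
    mean beta_ctx``; ``alpha~`` is reported as the product ``C~ * beta~``
    (i.e. with the mean net signals represented by the product of the mean
    conservation factor and mean absolute signal), which makes the identity
    ``alpha~ = C~ * beta~`` hold exactly at every radius.  The SD fields
    hold the dispersion of per-sample cerebellar ratios about the cortical
    mean reference.
    """

    radii_mm: np.ndarray
    C_ratio: np.ndarray
    C_ratio_sd: np.ndarray
    alpha_ratio: np.ndarray
    alpha_ratio_sd: np.ndarray
    beta_ratio: np.ndarray
    beta_ratio_sd: np.ndarray


def normalize_to_reference(cb_samples: dict, ctx_samples: dict,
                           radii_mm) -> NormalizedCurve:
    """Normalize cerebellar samples by the cortical mean per radius.

    ``cb_samples``/``ctx_samples`` map radius (mm) to arrays of per-sample
    ``(C, alpha, beta)`` triples, shape (n_samples, 3), evaluated on the
    identical radius grid (no interpolation is attempted).
    """
    radii_mm = np.asarray(radii_mm, float)
    for r in radii_mm:
        if r not in cb_samples or r not in ctx_samples:
            raise ValueError(
                f"radius {r} mm missing from one sample set; grids must match"
            )
    Cm, Cs, am, as_, bm, bs = [], [], [], [], [], []
    for r in radii_mm:
        cb = np.asarray(cb_samples[r], float)
        ctx = np.asarray(ctx_samples[r], float)
        ref = ctx.mean(axis=0)  # mean C, alpha, beta of the cortex
        if np.any(ref <= 0):
            raise ValueError(f"non-positive cortical reference at r={r} mm")
        c_ratio = cb[:, 0].mean() / ref[0]
        b_ratio = cb[:, 2].mean() / ref[2]
        Cm.append(c_ratio)
        bm.append(b_ratio)
        am.append(c_ratio * b_ratio)
        Cs.append((cb[:, 0] / ref[0]).std(ddof=1))
        as_.append((cb[:, 1] / ref[1]).std(ddof=1))
        bs.append((cb[:, 2] / ref[2]).std(ddof=1))
    return NormalizedCurve(
        radii_mm, np.array(Cm), np.array(Cs), np.array(am), np.array(as_),
        np.array(bm), np.array(bs),
    )
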