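"""Per-vertex sensitivity maps and single-dipole signal-norm histograms.

A sensitivity map colors every source vertex by the Euclidean sensor-space
norm of the signal a fixed-moment dipole (100 nAm by default) at that
vertex would produce, per modality.  EEG signals are average-referenced
before the norm.  Sources removed by the inner-skull exclusion carry NaN
(rendered black in the figures such maps emulate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import SourceSpace
from .cancelation import PhysiologicalConstants
from .forward import GainMatrix, average_reference


@dataclass
class SensitivityMap:
    """Per-vertex signal norms for a fixed dipole moment (one modality)."""

    values: np.ndarray  # per source-space vertex; NaN where excluded
    modality: str
    moment_nam: float
    surface: str = "unnamed"

    def kept_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


def sensitivity_map(G: GainMatrix, source_space: SourceSpace,
                    modality: str, moment_nam: float = 100.0,
                    reference_eeg: bool = True) -> SensitivityMap:
    """Norm of each unit column scaled to ``moment_nam`` nanoampere-meters."""
    from .sensors import MODALITIES

    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    block = G.modality_values(modality)
    if block.shape[0] == 0:
        raise ValueError(f"gain matrix has no {modality} channels")
    if modality == "eeg" and reference_eeg:
        block = average_reference(block)
    norms = np.linalg.norm(block, axis=0) * (moment_nam * 1e-9)
    values = np.full(source_space.n_sources, np.nan)
    values[G.source_indices] = norms
    return SensitivityMap(values, modality, moment_nam, source_space.surface)


def percentile_clip(map_: SensitivityMap, lo: float = 1.0, hi: float = 99.0):
    """Display range: (P_lo, P_hi) of the map's kept values.

    Percentiles use the linear-interpolation definition (numpy default).
    """
    vals = map_.kept_values()
    if vals.size == 0:
        raise ValueError("sensitivity map has no kept vertices")
    return tuple(np.percentile(vals, [lo, hi]))


@dataclass
class NormHistogram:
    """Density-normalized histogram of norms relative to the cortical median."""

    bin_edges: np.ndarray
    density: np.ndarray
    median_ratio: float
    exceedance_fraction: float

    def integral(self) -> float:
        return float((self.density * np.diff(self.bin_edges)).sum())


def norm_histogram(map_: SensitivityMap, reference_map: SensitivityMap,
                   n_bins: int = 100) -> NormHistogram:
    """Histogram of ``map_`` norms normalized to the reference map's median.

    Reports the ratio of medians and the fraction of ``map_`` vertices whose
    norm exceeds the reference (cortical) median.  Both maps must be the
    same modality.  Bins are ``n_bins`` equal widths spanning 0 to the
    pooled 99.5th percentile.
    """
    if map_.modality != reference_map.modality:
        raise ValueError("histogram maps must share a modality")
    vals = map_.kept_values()
    ref = reference_map.kept_values()
    ref_median = float(np.median(ref))
    if ref_median <= 0:
        raise ValueError("reference (cortical) median is zero")
    x = vals / ref_median
    pooled = np.concatenate([x, ref / ref_median])
    upper = float(np.percentile(pooled, 99.5))
    edges = np.linspace(0.0, max(upper, 1e-30), n_bins + 1)
    density, edges = np.histogram(np.clip(x, edges[0], edges[-1]),
                                  bins=edges, density=True)
    return NormHistogram(
        bin_edges=edges,
        density=density,
        median_ratio=float(np.median(x)),
        exceedance_fraction=float((x > 1.0).mean()),
    )
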