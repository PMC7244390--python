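# cerebsim

Simulation of M/EEG signal cancelation and sensitivity on folded cortical
and cerebellar surfaces.

## The problem

Whether cerebellar activity is detectable with MEG and EEG hinges on two
geometric facts. First, the cerebellar cortex is folded far more tightly
than the neocortex — individual folia are 1–2 mm wide — so current dipoles
on opposing fold walls point in nearly opposite directions and their sensor
signals cancel. Second, the cerebellum sits deeper and lower in the head
than most of the cerebrum, which weakens its signals further. Quantifying
these effects requires a surface model that actually resolves the folia;
conventional MRI segmentations smooth them away and therefore overestimate
the surviving signal.

`cerebsim` is a pipeline for studying exactly this: it generates synthetic
folded sheets (a cerebellum-like corrugated shell, a cortex-like gyrified
cap, and a smoothed-shell surrogate for outer-hull segmentations) inside a
three-shell spherical head, computes current-dipole forward solutions for a
306-channel MEG helmet (102 magnetometer + 204 planar-gradiometer channels)
and a 72-electrode EEG cap, and measures signal cancelation and sensitivity
with Monte Carlo activation designs. Everything runs from synthetic anatomy,
so the full analysis is reproducible on a laptop.

## The statistics

For `n` simultaneously active unit current dipoles with forward (gain)
columns `G[:, j]`:

* net signal `A_n = || Σ_j G[:, j] ||₂` — signal of simultaneous activation,
* absolute signal `B_n = Σ_j || G[:, j] ||₂` — sum of individual-activation
  norms,
* conservation factor `C = A/B ∈ [0, 1]` (cancelation index `I_c = 1 − C`),
* physiological norms `α = A·a_n·q₀/n`, `β = B·a_n·q₀/n`, which rescale a
  patch of area `a_n` to the invariant cortical current-dipole density
  `q₀ = 1 nAm/mm²`; `C = α/β` and both are invariant to source-grid density.

Two Monte Carlo designs drive these statistics: dipoles distributed
uniformly at random over a surface (`C` collapses roughly as `1/√n`), and
spatially coherent patches grown to area `πr²` for radii 1–30 mm (`β`
grows with patch area, `α ≈ C·β` roughly linearly with radius). Per-vertex
sensitivity maps use a fixed 100 nAm dipole per source with average-reference
EEG.

Forward solutions come from analytic sphere models (Sarvas' closed-form
field; three-shell Legendre-series potentials) or a three-compartment
boundary-element method with linear collocation and the isolated-skull
approach, validated against the analytic models.

## Worked example

A scaled-down cerebellum-like shell (8 mm body radius, folia at the
anatomical 2 mm wavelength), a magnetometer array, and a coherent-patch
experiment:

```python
import numpy as np
from cerebsim import (cerebellum_like, generate_folded_sheet,
                      build_source_space, decimate_source_space,
                      ExperimentDesign, run_coherent, summarize_curve,
                      compute_gain, ForwardEngine, generate_helmet_array)

rec = cerebellum_like(base_radius=8.0, center=(0.0, -40.0, -30.0),
                      lobule_wavelength=6.4, lobule_amplitude=0.96,
                      edge_length=0.2)
mesh = generate_folded_sheet(rec, inner_skull_radius_mm=80.0)
src = decimate_source_space(
    build_source_space(mesh, 0.080, min_dist_mm=5.0, surface="cerebellum"),
    20000)
mags = generate_helmet_array().subset("mag")
gain = compute_gain(src, mags, ForwardEngine())
print(f"surface area {mesh.area()*1e6:.0f} mm^2, "
      f"{int(src.kept.sum())} kept sources, gain {gain.shape}")

design = ExperimentDesign(condition="coherent", radii_mm=(2.0, 5.0, 10.0),
                          samples=100, seed=0, modalities=("mag",))
curve = summarize_curve(run_coherent(design, src, gain), "radius_mm")
for _, row in curve.iterrows():
    print(f"r = {row['radius_mm']:4.0f} mm   C = {row['C_mean']:.3f} "
          f"+/- {row['C_sd']:.3f}   alpha = {row['alpha_mean']:.2e} T")
```

prints

```
surface area 1879 mm^2, 20000 kept sources, gain (102, 20000)
r =    2 mm   C = 0.447 +/- 0.159   alpha = 1.45e-13 T
r =    5 mm   C = 0.390 +/- 0.125   alpha = 6.97e-13 T
r =   10 mm   C = 0.338 +/- 0.086   alpha = 2.40e-12 T
```

i.e. on this deeply folded sheet more than half of the signal already
cancels for 2 mm patches, the conservation factor keeps falling with patch
size, yet the net magnetometer signal `α` still *grows* with patch radius —
a larger activated area wins despite the increased cancelation.

The same analysis end-to-end (all surfaces, all modalities, distributed +
coherent designs, sensitivity maps, Markdown report) runs from the CLI:

```
cerebsim all --config run.yaml --out results/
```

with a YAML config overriding any subset of the defaults (see
`cerebsim.config.DEFAULT_CONFIG`).

## Layout

| module | contents |
| --- | --- |
| `cerebsim.meshes` | triangle meshes, icospheres/caps, angle-weighted normals, vertex areas, PLY/OFF I/O |
| `cerebsim.anatomy` | surface recipes and presets, folded-sheet generator, source spaces, exclusion, geodesic decimation, patch growth |
| `cerebsim.sensors` | head model, MEG helmet and EEG cap synthesis, CSV round trip |
| `cerebsim.forward` | Sarvas field, three-shell series, engines, gain matrices |
| `cerebsim.bem` | linear-collocation BEM (deflation, isolated-skull approach) |
| `cerebsim.cancelation` | A, B, C, α, β, cortex-normalized curves |
| `cerebsim.monte_carlo` | distributed/coherent designs, curve summaries, grid-convergence check |
| `cerebsim.sensitivity` | sensitivity maps, percentile clipping, norm histograms |
| `cerebsim.pipeline` / `cerebsim.cli` | orchestration, caching, manifest, report, `cerebsim` command |

Methodological details and modeling choices are documented in
`docs/methods.md`.
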