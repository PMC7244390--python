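# Methods

This note documents the models behind `cerebsim`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic setting
can and cannot say about real anatomy.

## Synthetic anatomy

### What the generator emulates

Three surface kinds stand in for the anatomical objects of interest:

* **cerebellum-like** — a deeply corrugated, nearly closed shell: parallel
  folia corrugations (wavelength 2 mm, amplitude 1 mm, matching the 1–2 mm
  width of real folia) superposed on parallel lobular folds (20 mm, 3 mm),
  on a 25 mm sphere whose center sits posterior-inferiorly at
  (0, −36, −26) mm. The cap spans 170°, leaving an opening toward the
  brainstem where the peduncles attach. The near-closed topology is
  essential, not cosmetic: by the vector-area theorem a one-sided cap
  retains a net dipole bias equal to its *flat* vector area no matter how
  deeply it is folded, which would place a floor under the conservation
  factor for distributed activations. The real cerebellar sheet (1.5–2 m
  unfolded) wraps its whole body, making surface normals near-isotropic at
  large scales, and the closed-shell surrogate reproduces that property.
* **cortex-like** — a cap of angular radius 120° high on a 58 mm sphere
  carrying a *disordered, isotropic* two-band fold field: a fine band at
  the gyral spacing (14 mm wavelength, 6 mm amplitude ≈ 12 mm sulcal
  depths) plus a coarse lobar undulation (48 mm, 4 mm). A periodic
  single-axis sinusoid was rejected during development: its perfectly
  coherent opposed walls cancel MEG signals almost completely once a patch
  spans a wavelength, while leaving EEG nearly uncancelled — neither
  matches folded-cortex behavior. Real gyrification is disordered and
  isotropic, and the coarse band matters: it keeps patch normals partially
  coherent at centimeter scales (as the smooth hemispheric envelope does),
  which is what makes the conservation factor decay gently (roughly like
  `1/r`) instead of collapsing.
* **smoothed-shell** — the cerebellum-like recipe with the folia band
  removed; the surrogate for outer-hull segmentations that smooth over
  folia. Comparing it against the folded shell isolates the folding effect.

The fold fields are deterministic given the recipe seed. The parallel
style writes the displacement `A_l sin(2πs/λ_l) + A_f sin(2πs/λ_f + φ)`
along a latitude coordinate of the cap; the isotropic style sums 24 plane
waves of the given wavelength with quasi-uniform directions and seeded
phases (RMS displacement `A/√2`, matching a sinusoid of amplitude `A`).

Caps are meshed by locally subdividing an icosphere until every edge is
below the recipe's edge length (enforced ≤ wavelength/10 so folds are
resolved), then displacing vertices radially. Realized fold crests are
checked against the inner-skull radius at generation time.

What the surrogates do **not** capture: real lobule geometry and lobule
labels, the cerebellar vermis/hemisphere distinction, cortical thickness
and sulcal asymmetries, the true gyrification index (ours is ≈ 1.8 against
≈ 2.5 for real cortex), and any subject-specific anatomy. Passing tests on
these surfaces therefore demonstrate the *mechanisms* (fold cancelation,
depth, smoothing bias) and the correctness of the machinery, not
subject-level numbers.

### Source spaces

Dipoles sit at mesh vertices with fixed orientations along angle-weighted
vertex normals; vertex areas are one third of incident face areas. Sources
within 5 mm of the inner skull are excluded (guarding the forward models'
validity near the boundary). Statistics run on farthest-point-sampled
source grids (default 60k cerebellum, 20k cortex and smoothed shell): the
icosphere parameterization under-samples steep fold walls in true-area
density, and the equal-moment scaling behind α/β assumes a density-uniform
grid. Farthest-point sampling (graph Dijkstra distances, lazy max-heap)
restores uniformity; every removed vertex's area is reassigned to its
geodesically nearest retained vertex, conserving total area to better than
1e-9 relative.

Coherent patches grow by ring-synchronous breadth-first accretion over the
kept-source adjacency graph, adding whole rings (ties broken by ascending
vertex index, making growth deterministic) until the accumulated vertex
area first reaches the flat-disc target `πr²`. The realized area `a_n` is
used in all statistics.

## Head model and sensors

The conductor is the standard three-shell concentric sphere: brain/skull/
scalp radii 80/85/92 mm, conductivities 0.3/0.006/0.3 S/m. MEG sensors sit
on a Fibonacci-lattice cap (102 sites, 108 mm radius, 115° coverage); each
site carries a radial magnetometer and two orthogonal planar gradiometers
modeled as two-point finite differences of the radial field component over
a 16.8 mm baseline (T/m). The EEG cap is a 72-electrode Fibonacci lattice
on the scalp sphere with 115° coverage; inferior coverage strongly affects
cerebellar EEG sensitivity and is deliberately a parameter, not a claim.
Measured layouts can be loaded from CSV instead.

## Forward models

* **Sphere engine (default and oracle).** MEG: Sarvas' closed form for the
  spherically symmetric conductor (radial dipoles exactly silent; the
  radial field component equals the bare Biot–Savart term — both used as
  test oracles). EEG: the concentric three-shell Legendre series with
  per-degree transfer factors from 5×5 interface systems, truncated when
  the geometric tail bound falls below 1e-8 relative; for equal
  conductivities it reduces to the homogeneous-sphere closed form, which
  the tests verify via generating-function sums.
* **BEM engine.** Linear-collocation boundary-element method on three
  nested closed meshes: analytically integrated per-triangle hat-function
  solid-angle weights, the on-surface principal-value closure (row sums
  2π) with the residual redistributed over incident vertices, deflation of
  the constant nullspace, and the isolated-skull approach (applied when
  σ_skull/σ_brain < 0.1, default on — the paper-era literature leaves ISA
  usage unstated, so it is an explicit flag). EEG is read at electrodes by
  closest-triangle barycentric interpolation; MEG adds the Geselowitz
  volume-current boundary integral (centroid quadrature) to the primary
  dipole field. The solver was cross-checked to machine precision against
  an independent implementation of the same published algorithm, and
  converges toward the analytic sphere solutions with mesh refinement
  (EEG: 7.4% → 5.8% → 1.7% at icosphere subdivisions 2/3/4 for a 40 mm
  tangential dipole; MEG: 0.03% at subdivision 3). The residual
  subdivision-3 EEG discrepancy is the known thin-skull magnitude bias of
  linear collocation when edge lengths (~10 mm) exceed the 5 mm skull
  thickness; it is a property of the method at that density, not of this
  implementation.

Gain matrices hold unit-dipole (1 A·m) columns per kept source, rows per
channel; EEG rows are stored unreferenced, and the average reference is an
explicit operator applied before every EEG norm (whether the original
cancelation computations were referenced is unstated in the literature;
referencing everywhere is the default, with a flag to disable).

## Cancelation statistics and Monte Carlo designs

`A`, `B`, `C = A/B`, `α = A·a_n·q₀/n`, `β = B·a_n·q₀/n` with
`q₀ = 1 nAm/mm²` (stored in SI as 1e-3 A/m; all internal geometry is SI,
mm appears only at the config boundary — this prevents the classic q₀
unit-slip). Norms are always per modality; magnetometer, gradiometer and
EEG channels are never pooled. For distributed (non-patch) sets, `a_n` is
the summed area of the active vertices, which preserves `C`'s invariance
and α's density semantics.

Both designs draw 200 activations per grid point by default. Distributed:
uniform sampling without replacement, `n` on a log grid from 1 to the
source count (larger requests are capped and logged). Coherent: patch
seeds drawn uniformly over kept vertices, repeats allowed (collisions are
immaterial at 200 samples over ≥ 10⁴ vertices), radii 1–30 mm. Summaries
report means and sample SDs (ddof 1).

Cortex-normalized curves divide cerebellar values by the cortical mean at
the same radius (unpaired — the samples are independent draws). The
summary `α̃` is reported as the product `C̃·β̃` (the mean net signal
represented by mean-C × mean-β), which makes the identity `α̃ = C̃β̃`
exact at every radius; per-sample ratio dispersions are reported as SDs.

The `1/√n` power-law check fits the log-log slope of mean `C` versus `n`
over 4 ≤ n ≤ 1000 and requires it within 30% of −1/2. A pointwise reading
(`C·√n` within ±30% of 1) would test the column-norm dispersion of the
particular geometry rather than the law; the slope tests the law itself.

## Mesh convergence and grid invariance

The decimation-convergence check compares coherent-patch sensor signals
between a dense source grid and its ~55% decimation. Problem size: a
geometrically scaled cerebellar shell (6 mm body radius with the lobular
band scaled in proportion; folia kept at the anatomical 2 mm) meshed at
0.065 mm edges (< wavelength/20), full grid 110k sources — a full-size
shell at that spacing would need ~2M sources. The compared quantity is the
physiological net signal with each dipole carrying its represented area ×
q₀ (the uniform-grid limit of the α scaling); the same surface region is
evaluated on both grids by activating every decimated source whose
assignment cell is majority-covered by the full-grid patch. Maximum
relative difference over 20 random 10 mm patches: ≈ 0.7% (magnetometers)
and ≈ 0.6% (EEG), comfortably under the 1% convergence criterion, and the
same machinery shows α and β agree across grid densities within 2%.

## Sensitivity maps and histograms

Per-vertex maps scale each unit column to 100 nAm (the net moment of a
~10 mm patch at conservation factor ~0.3) and take the Euclidean channel
norm; EEG uses all 72 electrodes (a subset near the head bottom would be a
claim about the original montage that the record does not support).
Excluded sources carry NaN. Display ranges clip at the 1st–99th
percentiles (linear-interpolation definition). Histograms normalize norms
to the median cortical norm, use 100 equal-width bins spanning 0 to the
pooled 99.5th percentile (binning is otherwise unstated in the
literature), integrate to one, and report the median ratio and the
fraction of cerebellar vertices exceeding the cortical median.

## Reproducibility and numerics

One global seed expands into per-stage child seeds via
`numpy.random.SeedSequence` spawning; identical config + seed reproduces
byte-identical CSV outputs, and gain matrices are cached by content hash
of (grid, sensors, engine). Degenerate inputs fail loudly: zero-area
faces, isolated vertices, disconnected meshes, open BEM boundaries,
sources outside or within 5 mm of the inner skull, mixed channel types in
one norm, `B = 0` activations, non-convergent series. Patch growth beyond
the surface's total area returns all kept sources with a warning.

## Known limitations

* Surfaces are spherically-based surrogates; absolute signal magnitudes
  and structure-specific numbers (e.g. the exact cerebellar-to-cortical
  signal ratio) depend on real anatomy and measured sensor layouts and are
  out of scope — only directions, identities, scaling laws and asymptotics
  are claimed.
* Sensor noise is not modeled; all norms are noiseless.
* MEG coils are point sensors (no pickup-coil integration).
* The BEM at coarse (subdivision-3) boundary meshes carries the method's
  thin-skull EEG magnitude bias; use subdivision 4 when EEG accuracy below
  ~5% matters.
* Inverse modeling is deliberately absent.
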