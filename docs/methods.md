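# Methods

`adaptherm` reconstructs the volumetric temperature distribution during
MR-guided thermal ablation by adapting a Pennes bioheat simulation to 2D
MR thermometry slices rotated uniformly around the applicator axis.  This
note records the model, the numerical choices, the synthetic study
conditions, and the limits of what the tests demonstrate.

## Model

### Bioheat equation in diffusion form

The Pennes bioheat transfer equation

ρc ∂T/∂t = ∇·(k∇T) + w_b c_b (T_a − T) + Q_m + Q_r

is reduced to

∂T/∂t = D ∇²T + P(x, t, T),  D = k/(ρc),

with `P` collecting perfusion, metabolic and regional heat terms divided by
ρc.  For protein phantoms Q_m = 0, and the treatment-specific source Q_r is
*never modelled explicitly*: because every acquired slice contains the
applicator axis, the observed heat profile itself drives the simulation.
Only the ratio D enters the diffusion term, so k, ρ and c are never needed
individually; `rho_c` (default 4·10⁶ J/(m³·K), water-like) scales only the
perfusion sink.

### Axial source from isotherms

Each temperature map is compressed into M isotherms (per side of the axis)
by a shortest-path filter (below).  For each point `r_i` on the axis the
orthogonal (in-plane radial) distances to all isotherm vertices in its
image row are summed; dividing by the maximum sum gives relative strengths
`q_i ∈ [0, 1]` with q = 1 where the isotherms bulge widest.  A single
scalar ablation parameter `T_max` converts them to absolute temperatures
`T_i = q_i · T_max`.

Two robustness rules temper the raw distance sums, both consequences of
the applicator artifact band (the ±2 px around the axis carry no valid
signal):

1. a vertex only enters the sums where the map comes within
   `deviation_tol` (3 °C, ≈3σ of thermometry noise) of its isovalue —
   elsewhere the path is merely hugging the band and measures nothing;
2. distances are measured from the first *valid* column on each side,
   removing the constant censoring offset that would otherwise give every
   row, heated or not, a spurious baseline strength.

The source is applied as an internal Dirichlet constraint: every voxel
within the physical applicator radius (`source_radius`, default 1 mm) of
an axis point is held at `max(T_i, current temperature)` *during* the
implicit solves.  Holding it during the solve (not just between steps)
makes the effective heat input independent of the time step; the max()
floors sub-baseline `T_i` and never cools tissue.

### Isotherm filter

For an isovalue `T_iso` the cost image is `|T − T_iso|` (invalid pixels
+∞).  The isotherm is the minimum-total-cost path that advances strictly
row by row (rows parallel to the needle axis), moving at most
`connectivity` (1) column sideways per row.  Summing signed deviations
along the path cancels zero-mean pixel noise, which is why the filter is
robust where naive thresholding is not.  On this row-DAG the shortest path
is computed by exact dynamic programming with a deterministic tie-break
toward the column nearest the axis; equivalence with exhaustive path
enumeration is tested on small grids.  Left and right half-images are
extracted separately (the band censors the middle).

The isovalue ladder has M = 8 rungs spanning 24 °C.  The ladder is
anchored one rung (span/(M−1) ≈ 3.4 °C) above the baseline temperature: an
isovalue exactly at baseline is degenerate, since the entire unheated
background (and the ambient Dirichlet boundary) matches it and the
minimum-cost path then tracks the image border instead of the heat zone.
Anchor, span and count are configurable.

### Inverse estimation

The parameter set P = {D, T_max} is fitted per acquired image by bounded
least squares (scipy's trust-region reflective variant of
Levenberg–Marquardt; bounds D ∈ [0.1, 5] mm²/s, T_max ∈ [80, 300] °C,
initial D = 1 mm²/s, initial T_max = baseline projected onto its bound).
The residual vector is T_E − T_R: the simulation advanced from the
accepted previous state under trial parameters, sampled trilinearly at the
isotherm vertices, minus the measured map values there.  The isotherms
choose *where* to sample (noise-robust contour positions); the measured
value is the reference, so residuals are unbiased by the pixel
quantisation of the contour.

Three orchestration details matter in practice, all exposed as estimator
parameters:

- **Window** (`window = 4`).  Near quasi-steady state the temperature
  field no longer depends on D at all (the Dirichlet steady state is
  scale-free), so a single short inter-acquisition interval carries almost
  no diffusivity information.  The fit at image i therefore re-simulates
  from the accepted state at image i−window and compares each of the most
  recent images at its own acquisition time.  `window = 1` is the strictly
  sequential per-image scheme (`adaptive_update`).
- **Warm-up gate** (`min_isovalues = 3`).  Until at least three isovalues
  have a genuine contour outside the artifact band, a fit can only lock
  onto the D/T_max trade-off ridge; such images are skipped, and while
  nothing has been fitted yet the model clock is not advanced, so the
  first accepted fit integrates the full heating history from baseline.
- **Consolidation** (`refine = True`).  The sequential fits track a
  narrow, curved valley in (D, T_max) and can stall anywhere along it.
  After the adaptive pass, the same objective accumulated over *all*
  acquisitions (replayed from baseline with the recorded per-image source
  profiles) is minimised by a coarse bounds-spanning grid search plus a
  local least-squares polish.  This is deterministic, makes the final
  estimate essentially independent of the initial guess (which is what
  makes the unrestricted-bounds and bad-initialisation robustness
  configurations behave), and produces the final reported volume.

Identifiability, honestly stated: with the near-axis region censored by
the artifact band, D and T_max compensate each other along a flat
diagonal valley; the temperature *field* is far better determined than
either parameter.  In the synthetic benchmarks the reconstructed necrosis
volume reaches Dice 0.92–1.00 across all parameter combinations, while
the recovered parameters are accurate for hot, well-spread ablations
(errors of a few percent) and degrade to roughly −25 % (D) / +10 %
(T_max) coupled errors for the coolest (T_max = 100 °C) conditions, where
all informative contours crowd the censored band.  The test suite asserts
strict recovery tolerances anyway and documents the failures rather than
hiding them.

### Solver

Crank–Nicolson in time, second-order central differences in space,
advanced by a Douglas-style three-sweep alternating-direction-implicit
(ADI) splitting; each sweep solves batches of tridiagonal systems with a
vectorised Thomas algorithm.  The scheme is unconditionally stable and
second order in space and time (verified against the closed-form Gaussian
diffusion kernel with observed order ≈ 2).  Crank–Nicolson is A- but not
L-stable: for arbitrarily rough fields at very large Courant numbers
transient over/undershoot is possible; with the smooth fields of this
application the solution stays within the physical bounds for dt up to
10 s (tested).  Exact mirror symmetry about the axis planes holds to
1e−9; x↔y *exchange* symmetry holds only to the O(dt²) splitting error
because the sweeps are ordered.

The perfusion sink a·(T_a − T), a = w_b c_b/(ρc) inside the known
vessel/tube mask, is split per the Crank–Nicolson average: the explicit
half and the constant part of the implicit half enter the first sweep's
right-hand side, the −a·T^{n+1} part enters the third sweep's diagonal.

Boundary condition: all six faces held at the ambient temperature
(Dirichlet), initial condition uniform baseline T₀.

## Synthetic phantom

The generator emulates the rotated-acquisition protocol on a bio-protein
phantom: 2D slices (default 8 orientations at k·22.5°, 2-s interval,
1 mm pixels) sampled from a forward simulation with known true parameters,
i.i.d. Gaussian pixel noise (default σ = 1 °C), and a corrupted
applicator band (±2 px replaced by clutter and marked invalid).  The true
source is an ellipsoidal axial profile (half-length 12 mm) driven to
`true_Tmax`; the generator reaches its setpoint within the first
acquisition interval (`ramp_duration_s`), as real MWA/RFA generators do —
a longer ramp would place the early images outside the method's own
T_max range [80, 300] °C and make the synthetic conditions unrepresentable
by construction.  An optional water-perfused tube (Eq. for w_b from pump
flow rate and tube geometry, water density 1000 kg/m³) produces the
heat-sink deformation of the necrosis zone.

To avoid the inverse crime, ground truth is always generated on a grid 2×
finer and a time step 4× finer than the fitting configuration, so data and
reconstruction never share a discretisation.  The true necrosis mask
thresholds the final noiseless volume at 55 °C (the conventional
coagulation point within the [50, 60] °C range).

What the generator does **not** emulate: Rician/phase-correlated MR noise,
B0 drift, coagulation chemistry (pH-dependent whitening), needle bending,
motion.  Passing tests therefore demonstrate correctness of the algorithm
under idealised acquisition geometry and Gaussian noise, not clinical
performance.

## Evaluation

Necrosis = T ≥ τ with τ ∈ [50, 60] °C.  Global mode picks the τ (0.5 °C
steps) maximising 3D Dice against the reference per phantom; median mode
finds the best 2D slice-wise τ per orientation (Dice between thresholded
simulated slice and thresholded measured map) and applies the median of
the eight.  Dice = 2TP/(2TP+FP+FN), defined as 1 for two empty masks.
SEM is reported at 95 % confidence: σ/√N · 1.96 with the n−1 variance.
Robustness configurations: 1–5 restrict the orientations
([0°,22.5°,45°,67.5°], [90°,112.5°,135°,157.5°], [0°,22.5°], [90°],
[22.5°]); 6 widens both search ranges to [0.1, 1000]; 7 starts from the
deliberately wrong D = 10 mm²/s, T_max = 500 °C.

## Problem sizes used in the test suite

The full test suite and the acceptance script are sized to run on a single
CPU in well under half an hour: fitting grids of 31³ voxels at 1 mm
(ground truth 61³ at 0.5 mm), 16–24 acquisitions at 2 s, solver dt 0.5 s
(truth 0.125 s); the solver correctness checks run up to 81³ and the
stability checks at the full 60³ production size.  All randomness flows
from explicit seeds; every reported number is recomputed at run time.

## Known limitations

- D and T_max are effective, discretisation-coupled parameters; only
  their combination is sharply determined by band-censored contour data.
- The global (single-valued) D cannot represent local heat sinks; the
  perfusion tube must be supplied as a known mask.
- The isotherm filter assumes one vertex per row (no closed contours) and
  monotone advance along the axis.
- The per-orientation median threshold uses the last acquired map of each
  orientation only.
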