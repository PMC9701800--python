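# adaptherm

Adaptive 3D bioheat simulation of MR thermometry for minimally-invasive
thermal ablation monitoring.

During MR-guided tumor ablation (RFA/MWA), 2D proton-resonance-frequency
(PRFS) temperature maps are acquired on planes rotated uniformly around the
applicator's main axis, so every image contains the heat source and the full
radial heat profile.  `adaptherm` turns that stream into a live volumetric
temperature map: each incoming 2D map is compressed into noise-robust
isotherms, and a 3D Pennes bioheat simulation in pure diffusion form,

∂T/∂t = D ∇²T + P(x, t, T),  D = k/(ρc),

is adapted to the data — no treatment-specific heat-source term is ever
modelled.  Instead, the observed isotherm geometry defines a relative axial
source profile q_i ∈ [0, 1] (normalised sums of the orthogonal distances
from axis points to the isotherms), scaled to absolute temperatures
T_i = q_i · T_max.  The two global parameters P = {D, T_max} are estimated
per image by bounded Levenberg–Marquardt-type least squares on the objective

f(P) = Σ_j [ T_E_j(P) − T_R_j ]²,

the difference between the simulated temperatures at the isotherm vertices
and the measured ones.  The predicted coagulation-necrosis volume is the
simulation thresholded in the [50, 60] °C range and is scored by Dice
against ground truth.  The solver is Crank–Nicolson with
alternating-direction-implicit sweeps and Thomas tridiagonal solves —
unconditionally stable, second order in space and time.

The package is aimed at researchers in interventional MR thermometry who
want a tested, deterministic reference implementation of this adaptive
reconstruction together with a synthetic rotated-acquisition phantom
generator (with known ground truth, artifact band, noise and optional
heat-sink tubes) for validation studies.

## Worked example

```python
from adaptherm import (PhantomSpec, generate_series,
                       AdaptiveBioheatEstimator)
from adaptherm.evaluation import best_threshold, dice

# synthetic phantom: true D = 1 mm^2/s, true T_max = 150 °C, 8 rotated
# orientations, 24 images every 2 s, sigma = 1 °C pixel noise; ground
# truth is generated on a 2x finer grid with a 4x finer time step
spec = PhantomSpec(true_D=1.0, true_Tmax=150.0, noise_sigma=1.0,
                   n_timepoints=24, fit_shape=(31, 31, 31), seed=1)
maps, truth = generate_series(spec)

est = AdaptiveBioheatEstimator(grid_shape=(31, 31, 31)).fit(maps)
print(f"D = {est.D_:.2f} mm^2/s, T_max = {est.T_max_:.0f} C")

truth_mask = truth.necrosis_on(est.volume_)
tau = best_threshold(est.volume_.field, truth_mask)
print(f"threshold = {tau:.1f} C, "
      f"Dice = {dice(est.volume_.field >= tau, truth_mask):.3f}")
```

Output:

```
D = 0.94 mm^2/s, T_max = 156 C
threshold = 56.0 C, Dice = 0.992
```

The estimator recovers the thermal diffusivity and the peak source
temperature of the hidden forward model from the noisy rotated 2D series
alone, and the predicted necrosis volume overlaps the true one at
Dice ≈ 0.99.  `est.fit_records_` holds the per-image fit log (SSE before
and after, iterations, skipped images); `est.predict(points)` samples the
final volume at arbitrary world coordinates.

The same pipeline is available from the shell:

```bash
adaptherm simulate    --config phantom.json --out run/
adaptherm reconstruct --series run/series --out run/recon --grid 31
adaptherm evaluate    --series run/series --truth run/ --out run/eval \
                      --configs all
```

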