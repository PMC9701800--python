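"""Synthetic rotated-thermometry phantom with known ground truth.

Stands in for a bio-protein ablation phantom imaged by 2D slices rotated
uniformly around the applicator axis: a baseline-temperature volume, an
ellipsoidal heat zone growing around the axis (driven by the package's own
forward bioheat solver with known true parameters), Gaussian pixel noise, a
corrupted band along the applicator artifact, and an optional water-perfused
tube acting as a heat sink.

To avoid the inverse crime, the ground-truth forward run uses a 2x finer
grid and a 4x finer time step than the fitting configuration that will be
estimated against it, so the generated data never share a discretisation
with the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bioheat
from .bioheat import SolverState, SourceProfile, TissueParams, perfusion_rate
from .geometry import SliceFrame, VolumeGrid, build_slice_frames, slice_to_world
from .thermometry import TemperatureMap

__all__ = [
    "HeatSinkSpec",
    "PhantomSpec",
    "GroundTruth",
    "generate_series",
    "analytic_gaussian_field",
    "corrupt_image",
]


@dataclass
class HeatSinkSpec:
    """A straight water-perfused tube parallel to the applicator axis."""

    offset_mm: float = 8.0         # distance of tube axis from applicator axis
    tube_radius_mm: float = 3.0
    tube_length_mm: float = 100.0
    flow_rate_m3s: float = 1.0e-6  # ~ 60 ml/min laboratory pump

    @property
    def w_b(self) -> float:
        return perfusion_rate(self.flow_rate_m3s, self.tube_radius_mm * 1e-3,
                              self.tube_length_mm * 1e-3)

    def mask(self, grid: VolumeGrid) -> np.ndarray:
        x, y, z = grid.axes
        xx, yy = np.meshgrid(x, y, indexing="ij")
        r2 = (xx - self.offset_mm) ** 2 + yy**2
        return np.broadcast_to(
            (r2 <= self.tube_radius_mm**2)[:, :, None], grid.shape
        ).copy()


@dataclass
class PhantomSpec:
    """Study conditions of one synthetic ablation phantom."""

    true_D: float = 1.0              # mm^2/s
    true_Tmax: float = 150.0         # °C
    baseline_T0: float = 21.0        # °C
    n_orientations: int = 8
    n_timepoints: int = 16
    acquisition_interval: float = 2.0  # s
    noise_sigma: float = 1.0         # °C
    artifact_half_width: int = 2     # px
    heat_sink: HeatSinkSpec | None = None
    seed: int = 0
    # fitting-side reference discretisation; generation runs 2x finer in
    # space and 4x finer in time (anti-inverse-crime)
    fit_shape: tuple[int, int, int] = (61, 61, 61)
    fit_spacing: float = 1.0
    fit_dt: float = 0.5
    source_half_length_mm: float = 12.0
    #: the generator reaches its temperature setpoint within the first
    #: acquisition interval (MWA/RFA power-up takes seconds)
    ramp_duration_s: float | None = None
    T_a: float = 25.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_orientations < 1:
            raise ValueError("n_orientations must be >= 1")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")

    @property
    def fine_grid(self) -> VolumeGrid:
        shape = tuple(2 * n - 1 for n in self.fit_shape)
        g = VolumeGrid(shape=shape, spacing=self.fit_spacing / 2.0)
        g.field[:] = self.baseline_T0
        return g

    @property
    def matrix(self) -> tuple[int, int]:
        return (self.fit_shape[2], self.fit_shape[0])

    def frames(self) -> list[SliceFrame]:
        return build_slice_frames(
            self.n_orientations, matrix=self.matrix,
            pixel_spacing=self.fit_spacing,
        )


@dataclass
class GroundTruth:
    """Noiseless forward trajectory and the true coagulation mask."""

    grid: VolumeGrid                       # fine generation grid (final field)
    trajectory: list[tuple[float, np.ndarray]]  # (time s, float32 field)
    necrosis: np.ndarray                   # bool, on the fine grid
    threshold: float
    spec: PhantomSpec

    def temperature_on(self, grid: VolumeGrid) -> np.ndarray:
        """Final true temperature resampled onto another grid (trilinear)."""
        from .geometry import sample_volume

        x, y, z = grid.axes
        pts = np.stack(np.meshgrid(x, y, z, indexing="ij"), axis=-1)
        vals, _ = sample_volume(self.grid, pts.reshape(-1, 3),
                                boundary_value=self.spec.baseline_T0)
        return vals.reshape(grid.shape)

    def necrosis_on(self, grid: VolumeGrid) -> np.ndarray:
        return self.temperature_on(grid) >= self.threshold


def _axial_profile(spec: PhantomSpec, z: np.ndarray) -> np.ndarray:
    """Ellipsoidal relative source strength along the axis, peak 1 at z=0."""
    u = z / spec.source_half_length_mm
    return np.sqrt(np.clip(1.0 - u**2, 0.0, None))


def _sample_frame(grid: VolumeGrid, frame: SliceFrame,
                  baseline: float) -> np.ndarray:
    from .geometry import sample_volume

    nr, nc = frame.matrix
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    px = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)
    pts = slice_to_world(frame, px)
    vals, _ = sample_volume(grid, pts, boundary_value=baseline)
    return vals.reshape(nr, nc)


def generate_series(
    spec: PhantomSpec,
    necrosis_threshold: float = 55.0,
) -> tuple[list[TemperatureMap], GroundTruth]:
    """Forward-simulate one phantom and acquire its rotated 2D series.

    Returns the time-ordered noisy maps (one rotated frame per acquisition,
    cycling through the orientations) and the noiseless ground truth
    (fine-grid trajectory at the acquisition times plus the thresholded
    true necrosis mask).  All randomness is fixed by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.fine_grid
    z = grid.axes[2]
    axis_pts = np.zeros((len(z), 3))
    axis_pts[:, 2] = z
    q = _axial_profile(spec, z)
    profile = SourceProfile(axis_points=axis_pts, q=q, q_max=1.0)

    params = TissueParams(D=spec.true_D, T_a=spec.T_a)
    sink_mask = None
    if spec.heat_sink is not None:
        params.w_b = spec.heat_sink.w_b
        sink_mask = spec.heat_sink.mask(grid)
    state = SolverState(
        volume=grid,
        dt=spec.fit_dt / 4.0,
        boundary_T=spec.baseline_T0,
        params=params,
        sink_mask=sink_mask,
    )
    ramp_end = (spec.ramp_duration_s if spec.ramp_duration_s is not None
                else spec.acquisition_interval)
    frames = spec.frames()

    maps: list[TemperatureMap] = []
    trajectory: list[tuple[float, np.ndarray]] = []
    steps_per_acq = int(round(spec.acquisition_interval / state.dt))
    for i in range(spec.n_timepoints):
        for _ in range(steps_per_acq):
            # linear power-up over the first part of the ablation, then hold
            ramp = 1.0 if ramp_end <= 0 else min(1.0, (state.time + state.dt)
                                                 / ramp_end)
            state.source = bioheat.absolute_source(profile,
                                                   ramp * spec.true_Tmax)
            state = bioheat.adi_step(state)
        trajectory.append((state.time,
                           state.volume.field.astype(np.float32)))
        frame = frames[i % spec.n_orientations]
        values = _sample_frame(state.volume, frame, spec.baseline_T0)
        if spec.noise_sigma > 0:
            values = values + rng.normal(0.0, spec.noise_sigma, values.shape)
        valid = np.ones(values.shape, dtype=bool)
        if spec.artifact_half_width > 0:
            c0 = int(round(frame.axis_column))
            lo = max(0, c0 - spec.artifact_half_width)
            hi = min(values.shape[1], c0 + spec.artifact_half_width + 1)
            # the applicator erases the signal: replace by heavy clutter
            values[:, lo:hi] = spec.baseline_T0 + rng.normal(
                0.0, 10.0, (values.shape[0], hi - lo))
            valid[:, lo:hi] = False
        maps.append(TemperatureMap(
            values=values, frame=frame, time_index=i,
            baseline_T0=spec.baseline_T0, valid_mask=valid,
        ))
    truth = GroundTruth(
        grid=state.volume,
        trajectory=trajectory,
        necrosis=state.volume.field >= necrosis_threshold,
        threshold=necrosis_threshold,
        spec=spec,
    )
    return maps, truth


def analytic_gaussian_field(
    t: float,
    D: float,
    amplitude: float,
    width0: float,
    baseline: float,
    grid: VolumeGrid,
) -> np.ndarray:
    """Closed-form free-space diffusion of an isotropic Gaussian bump.

    The initial excess ``amplitude * exp(-r^2 / (2 width0^2))`` evolves under
    dT/dt = D lap T into a Gaussian of per-axis variance ``width0^2 + 2 D t``
    whose amplitude shrinks as ``(width0^2 / (width0^2 + 2 D t))^{3/2}``,
    conserving the integral of the excess over baseline.  Used as the exact
    reference for solver convergence tests.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if width0 <= 0:
        raise ValueError("width0 must be positive")
    var = width0**2 + 2.0 * D * t
    x, y, z = grid.axes
    r2 = (x[:, None, None] ** 2 + y[None, :, None] ** 2
          + z[None, None, :] ** 2)
    amp = amplitude * (width0**2 / var) ** 1.5
    return baseline + amp * np.exp(-r2 / (2.0 * var))


def corrupt_image(
    tmap: TemperatureMap,
    mode: str = "outlier",
    magnitude: float = 20.0,
    seed: int = 0,
    n_pixels: int = 5,
) -> TemperatureMap:
    """Inject artifacts for robustness tests.

    mode="outlier": add +-magnitude spikes at ``n_pixels`` random valid
    pixels.  mode="dropout": zero one random image quadrant and mark it
    invalid.  ``magnitude = 0`` returns an identical copy.
    """
    if not np.isfinite(magnitude):
        raise ValueError("magnitude must be finite")
    out = tmap.copy()
    if magnitude == 0:
        return out
    rng = np.random.default_rng(seed)
    if mode == "outlier":
        valid = np.argwhere(out.valid_mask)
        pick = valid[rng.choice(len(valid), size=min(n_pixels, len(valid)),
                                replace=False)]
        signs = rng.choice([-1.0, 1.0], size=len(pick))
        out.values[pick[:, 0], pick[:, 1]] += signs * magnitude
    elif mode == "dropout":
        nr, nc = out.values.shape
        qr = rng.integers(0, 2)
        qc = rng.integers(0, 2)
        rs = slice(0, nr // 2) if qr == 0 else slice(nr // 2, nr)
        cs = slice(0, nc // 2) if qc == 0 else slice(nc // 2, nc)
        out.values[rs, cs] = 0.0
        out.valid_mask[rs, cs] = False
    else:
        raise ValueError("mode must be 'outlier' or 'dropout'")
    return out
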