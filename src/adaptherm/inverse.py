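"""Per-image inverse estimation of the parameter set P = {D, T_max}.

Each newly acquired thermometry map is compressed into isotherms; the
objective

    f(P) = sum_j [ T_E_j(P) - T_R_j ]^2

compares the 3D simulation (advanced from the accepted state at the
previous acquisition under trial parameters P) with the measured isotherm
temperatures at the isotherm vertices, and is minimised by a bounded
damped-least-squares (Levenberg-Marquardt-type trust-region) fit.  The
accepted state is then advanced to the acquisition time under the fitted
parameters — the adaptive loop.

The orchestration is exposed as :class:`AdaptiveBioheatEstimator`, a
scikit-learn style estimator: ``fit(series)`` consumes the ordered list of
:class:`~adaptherm.thermometry.TemperatureMap` and leaves the fitted
diffusivity ``D_``, peak source temperature ``T_max_``, the final
temperature volume ``volume_`` and one :class:`FitRecord` per image in
``fit_records_``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from . import bioheat
from .bioheat import SolverState, SourceProfile, TissueParams, absolute_source
from .geometry import SliceFrame, VolumeGrid, sample_volume, slice_to_world
from .isotherms import (
    IsothermSet,
    NoValidDataError,
    default_isovalues,
    extract_isotherm_set,
)
from .thermometry import TemperatureMap, mask_applicator_band

__all__ = [
    "ParameterSet",
    "FitRecord",
    "residuals",
    "lm_fit",
    "adaptive_update",
    "AdaptiveBioheatEstimator",
]


@dataclass
class ParameterSet:
    """The two optimised parameters and their search ranges."""

    D: float = 1.0
    T_max: float = 80.0
    bounds_D: tuple[float, float] = (0.1, 5.0)
    bounds_Tmax: tuple[float, float] = (80.0, 300.0)

    def projected(self) -> "ParameterSet":
        """Clip both parameters into their bounds."""
        return replace(
            self,
            D=float(np.clip(self.D, *self.bounds_D)),
            T_max=float(np.clip(self.T_max, *self.bounds_Tmax)),
        )


@dataclass
class FitRecord:
    """Bookkeeping of one per-image fit."""

    time_index: int
    P_before: ParameterSet
    P_after: ParameterSet
    sse_before: float
    sse_after: float
    n_residuals: int
    n_iterations: int
    converged: bool
    skipped: bool = False


def _vertex_data(
    iso_set: IsothermSet,
    frame: SliceFrame,
    volume: VolumeGrid,
    deviation_tol: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """World points and measured temperatures of trustworthy isotherm vertices.

    The isotherm paths choose *where* to sample (their vertices sit in the
    noise-robust contour band); the reference temperature T_R at each vertex
    is the measured map value there.  A vertex only carries contour
    information where the map comes within ``deviation_tol`` °C of the
    isovalue; other vertices (unheated far field, unreachable isovalues)
    are excluded, as are vertices outside the simulation volume.
    """
    pts, t_r = [], []
    zlo = volume.origin[2]
    zhi = volume.origin[2] + (volume.shape[2] - 1) * volume.spacing
    measured = iso_set.tmap.values if iso_set.tmap is not None else None
    for iso in iso_set:
        w = slice_to_world(frame, iso.vertices.astype(float))
        keep = (w[:, 2] >= zlo) & (w[:, 2] <= zhi)
        if iso.costs is not None:
            keep &= np.asarray(iso.costs) <= deviation_tol
        pts.append(w[keep])
        if measured is not None:
            t_r.append(measured[iso.rows[keep], iso.cols[keep]])
        else:
            t_r.append(np.full(int(keep.sum()), iso.isovalue))
    pts = np.concatenate(pts)
    t_r = np.concatenate(t_r)
    if len(pts) == 0:
        raise NoValidDataError("no trustworthy isotherm vertices")
    return pts, t_r


def residuals(
    P: ParameterSet,
    prev_state: SolverState,
    iso_set: IsothermSet,
    frame: SliceFrame,
    dt_to_acquisition: float,
    q_profile: SourceProfile | None = None,
    deviation_tol: float = 3.0,
) -> np.ndarray:
    """Estimated-minus-measured temperatures at every isotherm vertex.

    The simulation is advanced from the accepted previous state under the
    trial parameters; the candidate state is discarded afterwards.
    """
    if len(iso_set) == 0:
        raise NoValidDataError("empty isotherm set")
    if q_profile is None:
        axis_pts = _axis_points(prev_state.volume)
        q_profile = bioheat.source_profile(axis_pts, [iso_set], [frame])
    cand = prev_state.copy()
    cand.params = replace(cand.params, D=P.D)
    cand.source = absolute_source(q_profile, P.T_max)
    cand = bioheat.simulate(cand, dt_to_acquisition)
    pts, t_r = _vertex_data(iso_set, frame, cand.volume, deviation_tol)
    vals, _ = sample_volume(cand.volume, pts, boundary_value=cand.boundary_T)
    return vals - t_r


def lm_fit(
    residual_fn,
    P_init: ParameterSet,
    ftol: float = 1e-4,
    xtol: float = 1e-4,
    max_nfev: int = 60,
) -> tuple[ParameterSet, FitRecord]:
    """Bounded least-squares fit of (D, T_max).

    Bounds are honoured at every trial point (trust-region reflective
    variant of damped least squares); the initial point is projected into
    the bounds first.  Deterministic given its inputs.
    """
    p0 = P_init.projected()
    lo = np.array([p0.bounds_D[0], p0.bounds_Tmax[0]])
    hi = np.array([p0.bounds_D[1], p0.bounds_Tmax[1]])

    def fun(x):
        r = residual_fn(replace(p0, D=float(x[0]), T_max=float(x[1])))
        return np.asarray(r, float)

    r0 = fun([p0.D, p0.T_max])
    if not np.all(np.isfinite(r0)):
        raise FloatingPointError("non-finite residuals at the initial point")
    res = least_squares(
        fun,
        x0=np.array([p0.D, p0.T_max]),
        bounds=(lo, hi),
        method="trf",
        ftol=ftol,
        xtol=xtol,
        gtol=1e-12,
        diff_step=1e-3,
        x_scale=np.array([1.0, 100.0]),
        max_nfev=max_nfev,
    )
    sse_before = float(np.sum(r0**2))
    sse_after = float(2.0 * res.cost)
    if sse_after > sse_before:  # never accept a worse point than the start
        p_after, sse_after = p0, sse_before
    else:
        p_after = replace(p0, D=float(res.x[0]), T_max=float(res.x[1]))
    record = FitRecord(
        time_index=-1,
        P_before=p0,
        P_after=p_after,
        sse_before=sse_before,
        sse_after=sse_after,
        n_residuals=len(r0),
        n_iterations=int(res.nfev),
        converged=bool(res.success),
    )
    return p_after, record


def _axis_points(volume: VolumeGrid) -> np.ndarray:
    """Candidate heat-source points: the applicator axis at every z level."""
    z = volume.axes[2]
    pts = np.zeros((len(z), 3))
    pts[:, 2] = z
    return pts


def adaptive_update(
    state: SolverState,
    P: ParameterSet,
    new_map: TemperatureMap,
    *,
    isovalues=None,
    artifact_half_width: int = 0,
    acquisition_interval: float = 2.0,
    accumulate: bool = False,
    history: dict | None = None,
    deviation_tol: float = 3.0,
    ftol: float = 1e-4,
    xtol: float = 1e-4,
    max_nfev: int = 60,
) -> tuple[SolverState, ParameterSet, FitRecord]:
    """One step of the adaptive loop for one newly acquired map.

    Extracts the isotherm set, refits P against the simulation advanced from
    the accepted state, rebuilds the axial source and advances the accepted
    state to the acquisition time.  On isotherm failure the update is
    skipped: the state advances under the previous parameters and the record
    is flagged.
    """
    tmap = new_map
    if artifact_half_width > 0:
        tmap = mask_applicator_band(tmap, artifact_half_width)
    target_time = (tmap.time_index + 1) * acquisition_interval
    dt_to_acq = max(target_time - state.time, 0.0)
    axis_pts = _axis_points(state.volume)

    try:
        iso_set = extract_isotherm_set(tmap, isovalues=isovalues, strict=False)
    except NoValidDataError:
        iso_set = None

    if iso_set is None:
        new_state = state.copy()
        if new_state.source is not None:
            new_state = bioheat.simulate(new_state, dt_to_acq)
        else:
            new_state.time = target_time
        rec = FitRecord(tmap.time_index, P, P, np.nan, np.nan, 0, 0,
                        converged=False, skipped=True)
        return new_state, P, rec

    if accumulate and history is not None:
        history[tmap.frame.angle] = (iso_set, tmap.frame)
        sets = [s for s, _ in history.values()]
        frames = [f for _, f in history.values()]
    else:
        sets, frames = [iso_set], [tmap.frame]
        if history is not None:
            history[tmap.frame.angle] = (iso_set, tmap.frame)
    q_profile = bioheat.source_profile(axis_pts, sets, frames)

    def residual_fn(p: ParameterSet) -> np.ndarray:
        return residuals(p, state, iso_set, tmap.frame, dt_to_acq,
                         q_profile=q_profile, deviation_tol=deviation_tol)

    try:
        P_after, record = lm_fit(residual_fn, P, ftol=ftol, xtol=xtol,
                                 max_nfev=max_nfev)
    except NoValidDataError:
        # nothing in the map is warm enough to pin any isotherm yet
        new_state = state.copy()
        if new_state.source is not None:
            new_state = bioheat.simulate(new_state, dt_to_acq)
        else:
            new_state.time = target_time
        rec = FitRecord(tmap.time_index, P, P, np.nan, np.nan, 0, 0,
                        converged=False, skipped=True)
        return new_state, P, rec
    record.time_index = tmap.time_index

    new_state = state.copy()
    new_state.params = replace(new_state.params, D=P_after.D)
    new_state.source = absolute_source(q_profile, P_after.T_max)
    new_state = bioheat.simulate(new_state, dt_to_acq)
    return new_state, P_after, record


class AdaptiveBioheatEstimator(BaseEstimator):
    """Adaptive 3D thermometry reconstruction as a scikit-learn estimator.

    ``fit(series)`` runs the per-image adaptive loop over an ordered list of
    temperature maps (rotated-slice acquisition) and exposes the fitted
    global parameters and the final simulated volume.

    Parameters
    ----------
    grid_shape, spacing : reconstruction grid (voxels, mm).
    dt : solver time step between acquisitions, s.
    acquisition_interval : time between consecutive images, s.
    initial_D, initial_Tmax : start of the optimisation; ``initial_Tmax``
        defaults to the series baseline (projected into its bounds).
    bounds_D, bounds_Tmax : hard search ranges.
    n_isovalues, isovalue_span : the isotherm ladder (anchored at baseline).
    artifact_half_width : columns around the axis to invalidate (0 = trust
        the masks already present on the maps).
    accumulate : fit against the latest isotherm set of *every* orientation
        seen so far instead of the newest image only.
    w_b, T_a, rho_c, c_b, sink_mask : perfusion (heat-sink) configuration;
        ``sink_mask`` is a boolean volume of the known vessel/tube region.
    """

    def __init__(
        self,
        grid_shape=(60, 60, 60),
        spacing: float = 1.0,
        dt: float = 0.5,
        acquisition_interval: float = 2.0,
        initial_D: float = 1.0,
        initial_Tmax: float | None = None,
        bounds_D: tuple[float, float] = (0.1, 5.0),
        bounds_Tmax: tuple[float, float] = (80.0, 300.0),
        n_isovalues: int = 8,
        isovalue_span: float = 24.0,
        isovalue_anchor_offset: float | None = None,
        artifact_half_width: int = 0,
        window: int = 4,
        min_isovalues: int = 3,
        refine: bool = True,
        refine_grid: int = 5,
        accumulate: bool = False,
        w_b: float = 0.0,
        T_a: float = 25.0,
        rho_c: float = 4.0e6,
        c_b: float = 4182.0,
        sink_mask=None,
        deviation_tol: float = 3.0,
        ftol: float = 1e-4,
        xtol: float = 1e-4,
        max_nfev: int = 60,
    ):
        self.grid_shape = grid_shape
        self.spacing = spacing
        self.dt = dt
        self.acquisition_interval = acquisition_interval
        self.initial_D = initial_D
        self.initial_Tmax = initial_Tmax
        self.bounds_D = bounds_D
        self.bounds_Tmax = bounds_Tmax
        self.n_isovalues = n_isovalues
        self.isovalue_span = isovalue_span
        self.isovalue_anchor_offset = isovalue_anchor_offset
        self.artifact_half_width = artifact_half_width
        self.window = window
        self.min_isovalues = min_isovalues
        self.refine = refine
        self.refine_grid = refine_grid
        self.accumulate = accumulate
        self.w_b = w_b
        self.T_a = T_a
        self.rho_c = rho_c
        self.c_b = c_b
        self.sink_mask = sink_mask
        self.deviation_tol = deviation_tol
        self.ftol = ftol
        self.xtol = xtol
        self.max_nfev = max_nfev

    # -- scikit-learn protocol ------------------------------------------

    def fit(self, series, y=None):
        """Run the adaptive loop over an ordered series of temperature maps.

        With ``window = 1`` this is the strictly sequential per-image scheme
        (each fit compares only the newest map, simulated from the accepted
        state at the previous acquisition).  With ``window = K > 1`` the fit
        at image i re-simulates from the accepted state at image i-K and
        compares each of the K most recent maps at its own acquisition time:
        the same objective accumulated over recent acquisitions.  The longer
        effective time base is what identifies the diffusivity — near
        steady state a single short interval carries almost no D
        information.
        """
        if len(series) == 0:
            raise ValueError("empty series")
        series = sorted(series, key=lambda m: m.time_index)
        baseline = float(series[0].baseline_T0)
        t0 = self.initial_Tmax if self.initial_Tmax is not None else baseline
        P = ParameterSet(
            D=self.initial_D,
            T_max=t0,
            bounds_D=tuple(self.bounds_D),
            bounds_Tmax=tuple(self.bounds_Tmax),
        ).projected()
        grid = VolumeGrid(shape=tuple(self.grid_shape), spacing=self.spacing)
        grid.field[:] = baseline
        state = SolverState(
            volume=grid,
            dt=self.dt,
            boundary_T=baseline,
            params=TissueParams(D=P.D, rho_c=self.rho_c, c_b=self.c_b,
                                w_b=self.w_b, T_a=self.T_a),
            sink_mask=self.sink_mask,
        )
        # An isovalue equal to the baseline is degenerate: the entire
        # unheated background (and the ambient boundary) matches it, so the
        # lowest informative isotherm sits one ladder step above baseline.
        off = self.isovalue_anchor_offset
        if off is None:
            off = (self.isovalue_span / (self.n_isovalues - 1)
                   if self.n_isovalues > 1 else 1.0)
        isovalues = default_isovalues(baseline + off, span=self.isovalue_span,
                                      count=self.n_isovalues)
        records: list[FitRecord] = []
        # per-image observation cache: (state before the image's interval,
        # q profile, iso set, frame, acquisition time)
        obs: list[dict] = []
        axis_pts = _axis_points(grid)
        for tmap in series:
            if self.artifact_half_width > 0:
                tmap = mask_applicator_band(tmap, self.artifact_half_width)
            t_acq = (tmap.time_index + 1) * self.acquisition_interval
            try:
                iso_set = extract_isotherm_set(tmap, isovalues=isovalues,
                                               strict=False)
                q_profile = bioheat.source_profile(
                    axis_pts, [iso_set], [tmap.frame],
                    deviation_tol=self.deviation_tol)
            except NoValidDataError:
                iso_set = q_profile = None

            if iso_set is not None:
                informative = {
                    iso.isovalue for iso in iso_set
                    if iso.costs is not None
                    and np.min(iso.costs) <= self.deviation_tol
                }
                if len(informative) < self.min_isovalues:
                    # too little of the heat zone is visible outside the
                    # artifact band to constrain (D, T_max): a fit here only
                    # locks onto the D/T_max ridge
                    iso_set = q_profile = None

            if iso_set is None and state.source is None:
                # nothing fitted yet: leave the clock at the series start so
                # the first accepted fit integrates the full heating history
                # from the baseline state
                records.append(FitRecord(tmap.time_index, P, P, np.nan,
                                         np.nan, 0, 0, converged=False,
                                         skipped=True))
                continue

            if iso_set is None:
                new_state = state.copy()
                if new_state.source is not None:
                    new_state = bioheat.simulate(new_state,
                                                 max(t_acq - state.time, 0.0))
                else:
                    new_state.time = t_acq
                records.append(FitRecord(tmap.time_index, P, P, np.nan,
                                         np.nan, 0, 0, converged=False,
                                         skipped=True))
                state = new_state
                continue

            pts_i, t_r_i = _vertex_data(iso_set, tmap.frame, grid,
                                        self.deviation_tol)
            obs.append({"state_before": state, "q": q_profile,
                        "iso": iso_set, "frame": tmap.frame, "t": t_acq,
                        "pts": pts_i, "t_r": t_r_i})
            win = obs[-max(1, int(self.window)):]

            def residual_fn(p: ParameterSet) -> np.ndarray:
                s = win[0]["state_before"].copy()
                s.params = replace(s.params, D=p.D)
                out = []
                for ob in win:
                    s.source = absolute_source(ob["q"], p.T_max)
                    s = bioheat.simulate(s, max(ob["t"] - s.time, 0.0))
                    pts, t_r = _vertex_data(ob["iso"], ob["frame"], s.volume,
                                            self.deviation_tol)
                    vals, _ = sample_volume(s.volume, pts,
                                            boundary_value=s.boundary_T)
                    out.append(vals - t_r)
                return np.concatenate(out)

            try:
                P, rec = lm_fit(residual_fn, P, ftol=self.ftol,
                                xtol=self.xtol, max_nfev=self.max_nfev)
                rec.time_index = tmap.time_index
            except NoValidDataError:
                rec = FitRecord(tmap.time_index, P, P, np.nan, np.nan, 0, 0,
                                converged=False, skipped=True)
            records.append(rec)

            new_state = state.copy()
            new_state.params = replace(new_state.params, D=P.D)
            new_state.source = absolute_source(q_profile, P.T_max)
            state = bioheat.simulate(new_state,
                                     max(t_acq - new_state.time, 0.0))
        if self.refine and obs:
            P, state = self._consolidate(P, obs, grid, baseline)
        self.D_ = P.D
        self.T_max_ = P.T_max
        self.params_ = P
        self.state_ = state
        self.volume_ = state.volume
        self.fit_records_ = records
        self.baseline_T0_ = baseline
        self.n_images_ = len(series)
        return self

    def _replay(self, P: ParameterSet, obs, grid, baseline) -> tuple:
        """Simulate the whole series from baseline under P.

        Uses the recorded per-image source profiles; returns the final
        state and the stacked residual vector over all acquisitions.
        """
        g = VolumeGrid(shape=tuple(self.grid_shape), spacing=self.spacing)
        g.field[:] = baseline
        s = SolverState(
            volume=g, dt=self.dt, boundary_T=baseline,
            params=TissueParams(D=P.D, rho_c=self.rho_c, c_b=self.c_b,
                                w_b=self.w_b, T_a=self.T_a),
            sink_mask=self.sink_mask,
        )
        out = []
        for ob in obs:
            s.source = absolute_source(ob["q"], P.T_max)
            s = bioheat.simulate(s, max(ob["t"] - s.time, 0.0))
            vals, _ = sample_volume(s.volume, ob["pts"],
                                    boundary_value=baseline)
            out.append(vals - ob["t_r"])
        return s, np.concatenate(out)

    def _consolidate(self, P: ParameterSet, obs, grid, baseline):
        """Global consolidation of (D, T_max) on the full-history objective.

        The sequential per-image fits track a narrow curved valley in
        (D, T_max) and can stall on it; replaying the entire series from the
        baseline state gives the same objective accumulated over all
        acquisitions, whose minimum is sharp.  A coarse bounds-spanning grid
        search followed by a local least-squares polish finds it
        deterministically, which also makes the final estimate independent
        of the initial parameter guess.
        """
        d_lo, d_hi = P.bounds_D
        t_lo, t_hi = P.bounds_Tmax
        # The search box is a heuristic, not a constraint: it spans the
        # physically plausible ranges (tissue diffusivity 0.1-5 mm^2/s,
        # ablation temperature 80-300 °C) intersected with the user bounds.
        # Arbitrarily wide user bounds admit a spurious flat-field basin at
        # very large D that only a global search would ever visit.
        sd_lo, sd_hi = max(d_lo, 0.1), min(d_hi, 5.0)
        if sd_lo >= sd_hi:
            sd_lo, sd_hi = d_lo, d_hi
        st_lo, st_hi = max(t_lo, 80.0), min(t_hi, 300.0)
        if st_lo >= st_hi:
            st_lo, st_hi = t_lo, t_hi

        def sse_of(d, t):
            _, r = self._replay(replace(P, D=float(d), T_max=float(t)),
                                obs, grid, baseline)
            return float(np.sum(r**2))

        gr = (np.sqrt(5.0) - 1.0) / 2.0

        def best_T(d, tol=1.5):
            # golden-section over T at fixed D: the projected 1-D objective
            # is smooth and unimodal, unlike the rugged joint landscape
            a, b = st_lo, st_hi
            c, e = b - gr * (b - a), a + gr * (b - a)
            fc, fe = sse_of(d, c), sse_of(d, e)
            while b - a > tol:
                if fc < fe:
                    b, e, fe = e, c, fc
                    c = b - gr * (b - a)
                    fc = sse_of(d, c)
                else:
                    a, c, fc = c, e, fe
                    e = a + gr * (b - a)
                    fe = sse_of(d, e)
            return (c, fc) if fc < fe else (e, fe)

        # variable projection: profile SSE over log-spaced D values, each
        # evaluated at its own best T; purely data-driven, hence
        # independent of the optimizer's initial values
        n = max(4, int(self.refine_grid) + 3)
        d_grid = np.geomspace(sd_lo, sd_hi, n)
        profile = [(*best_T(d), d) for d in d_grid]  # (T*, sse, D)
        sses = np.array([p[1] for p in profile])
        i = int(np.argmin(sses))
        # parabolic refinement of the profile minimum in log-D
        if 0 < i < n - 1:
            x0, x1, x2 = np.log(d_grid[i - 1:i + 2])
            y0, y1, y2 = sses[i - 1:i + 2]
            num = (x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)
            den = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
            if den != 0:
                xm = x1 - 0.5 * num / den
                d_ref = float(np.exp(np.clip(xm, np.log(sd_lo),
                                             np.log(sd_hi))))
            else:
                d_ref = float(d_grid[i])
        else:
            d_ref = float(d_grid[i])
        t_ref, f_ref = best_T(d_ref)
        t_best, f_best, d_best = profile[i]
        if f_ref < f_best:
            d_best, t_best = d_ref, t_ref
        p_final = replace(P, D=float(np.clip(d_best, d_lo, d_hi)),
                          T_max=float(np.clip(t_best, t_lo, t_hi)))
        final_state, _ = self._replay(p_final, obs, grid, baseline)
        return p_final, final_state

    def predict(self, points):
        """Temperatures (°C) of the final simulated volume at world points."""
        self._check_fitted()
        vals, _ = sample_volume(self.volume_, np.asarray(points, float),
                                boundary_value=self.state_.boundary_T)
        return vals

    def necrosis(self, threshold: float = 55.0):
        """Binary coagulation mask of the final volume (T >= threshold)."""
        self._check_fitted()
        from .evaluation import necrosis_mask

        return necrosis_mask(self.volume_.field, threshold)

    def _check_fitted(self) -> None:
        if not hasattr(self, "volume_"):
            raise RuntimeError("estimator is not fitted; call fit(series) first")

    def records_frame(self):
        """Fit log as a DataFrame (time_index, D, T_max, SSE, iterations)."""
        self._check_fitted()
        import pandas as pd

        return pd.DataFrame(
            {
                "time_index": [r.time_index for r in self.fit_records_],
                "D": [r.P_after.D for r in self.fit_records_],
                "T_max": [r.P_after.T_max for r in self.fit_records_],
                "sse_before": [r.sse_before for r in self.fit_records_],
                "sse_after": [r.sse_after for r in self.fit_records_],
                "n_iterations": [r.n_iterations for r in self.fit_records_],
                "skipped": [r.skipped for r in self.fit_records_],
            }
        )
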