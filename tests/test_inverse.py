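import numpy as np
import pytest

from adaptherm.bioheat import SolverState, TissueParams, absolute_source
from adaptherm.geometry import VolumeGrid
from adaptherm.inverse import (
    AdaptiveBioheatEstimator,
    ParameterSet,
    adaptive_update,
    lm_fit,
    residuals,
)
from adaptherm.isotherms import extract_isotherm_set, default_isovalues
from adaptherm.phantom import PhantomSpec, generate_series
from adaptherm import bioheat
from adaptherm.inverse import _axis_points


class TestParameterSet:
    def test_projection_into_bounds(self):
        p = ParameterSet(D=10.0, T_max=500.0).projected()
        assert p.D == 5.0
        assert p.T_max == 300.0

    def test_projection_respects_custom_bounds(self):
        p = ParameterSet(D=10.0, T_max=500.0, bounds_D=(0.1, 1000.0),
                         bounds_Tmax=(0.1, 1000.0)).projected()
        assert p.D == 10.0
        assert p.T_max == 500.0


class TestLmFit:
    def test_quadratic_toy_recovers_closed_form_minimum(self):
        def resid(p):
            return np.array([p.D - 2.0, (p.T_max - 150.0) / 50.0])

        p, rec = lm_fit(resid, ParameterSet(D=1.0, T_max=100.0))
        assert p.D == pytest.approx(2.0, abs=1e-3)
        assert p.T_max == pytest.approx(150.0, abs=0.1)
        assert rec.sse_after <= rec.sse_before
        assert rec.converged

    def test_converged_start_returns_immediately(self):
        def resid(p):
            return np.array([0.0, 0.0])

        p, rec = lm_fit(resid, ParameterSet(D=1.5, T_max=120.0))
        assert p.D == pytest.approx(1.5)
        assert p.T_max == pytest.approx(120.0)

    def test_out_of_bounds_start_projected(self):
        def resid(p):
            return np.array([p.D - 2.0, (p.T_max - 150.0) / 50.0])

        p, rec = lm_fit(resid, ParameterSet(D=10.0, T_max=500.0))
        assert 0.1 <= p.D <= 5.0
        assert 80.0 <= p.T_max <= 300.0

    def test_nonfinite_residuals_raise(self):
        def resid(p):
            return np.array([np.nan])

        with pytest.raises(FloatingPointError):
            lm_fit(resid, ParameterSet())

    def test_deterministic(self):
        def resid(p):
            return np.array([np.sin(p.D) - 0.3, (p.T_max - 141.0) / 30.0])

        p1, r1 = lm_fit(resid, ParameterSet(D=0.5, T_max=90.0))
        p2, r2 = lm_fit(resid, ParameterSet(D=0.5, T_max=90.0))
        assert (p1.D, p1.T_max) == (p2.D, p2.T_max)
        assert r1.n_iterations == r2.n_iterations


@pytest.fixture(scope="module")
def tiny_phantom():
    spec = PhantomSpec(true_D=1.0, true_Tmax=150.0, noise_sigma=0.0,
                       n_timepoints=6, n_orientations=2,
                       fit_shape=(31, 31, 31), seed=11)
    maps, truth = generate_series(spec)
    return spec, maps, truth


class TestResiduals:
    def _setup(self, maps, n=31):
        grid = VolumeGrid(shape=(n, n, n))
        grid.field[:] = 21.0
        state = SolverState(volume=grid, dt=0.5, boundary_T=21.0,
                            params=TissueParams(D=1.0))
        m = maps[-1]
        iso = extract_isotherm_set(m, default_isovalues(21.0 + 24.0 / 7),
                                   strict=False)
        q = bioheat.source_profile(_axis_points(grid), [iso], [m.frame])
        return state, m, iso, q

    def test_constant_offset_field_gives_constant_residuals(self, tiny_phantom):
        _, maps, _ = tiny_phantom
        state, m, iso, q = self._setup(maps)
        # a state whose field is uniformly 2 °C above every measured value:
        # simulate nothing (dt 0) and shift the measured map instead
        state.volume.field[:] = 21.0
        shifted = m.copy()
        shifted.values = state.volume.field[0, 0, 0] - 2.0 + 0.0 * m.values
        iso2 = extract_isotherm_set(shifted, [19.0], strict=False)
        r = residuals(ParameterSet(D=1.0, T_max=80.0), state, iso2, m.frame,
                      0.0, q_profile=q)
        np.testing.assert_allclose(r, 2.0, atol=1e-9)

    def test_forward_model_self_consistency(self, tiny_phantom):
        spec, maps, _ = tiny_phantom
        state, m, iso, q = self._setup(maps)
        # advance the accepted state under truth for all but the last image
        for prev in maps[:-1]:
            iso_p = extract_isotherm_set(
                prev, default_isovalues(21.0 + 24.0 / 7), strict=False)
            qp = bioheat.source_profile(_axis_points(state.volume), [iso_p],
                                        [prev.frame])
            state.source = absolute_source(qp, spec.true_Tmax)
            state = bioheat.simulate(state, 2.0)
        p_true = ParameterSet(D=spec.true_D, T_max=spec.true_Tmax)
        r_true = residuals(p_true, state, iso, m.frame, 2.0, q_profile=q)
        from dataclasses import replace

        r_pert = residuals(replace(p_true, D=spec.true_D * 1.5), state, iso,
                           m.frame, 2.0, q_profile=q)
        assert np.sum(r_true**2) < np.sum(r_pert**2)


class TestAdaptiveUpdate:
    def test_first_image_initialisation_path(self, tiny_phantom):
        _, maps, _ = tiny_phantom
        grid = VolumeGrid(shape=(31, 31, 31))
        grid.field[:] = 21.0
        state = SolverState(volume=grid, dt=0.5, boundary_T=21.0,
                            params=TissueParams(D=1.0))
        P = ParameterSet(D=1.0, T_max=80.0)
        new_state, P1, rec = adaptive_update(state, P, maps[0])
        assert rec.time_index == 0
        assert new_state.time == pytest.approx(2.0)
        assert rec.skipped or rec.sse_after <= rec.sse_before

    def test_corrupted_image_is_skipped_not_fatal(self, tiny_phantom):
        _, maps, _ = tiny_phantom
        grid = VolumeGrid(shape=(31, 31, 31))
        grid.field[:] = 21.0
        state = SolverState(volume=grid, dt=0.5, boundary_T=21.0,
                            params=TissueParams(D=1.0))
        bad = maps[0].copy()
        bad.valid_mask[:] = False
        P = ParameterSet(D=1.0, T_max=80.0)
        new_state, P1, rec = adaptive_update(state, P, bad)
        assert rec.skipped
        assert (P1.D, P1.T_max) == (P.D, P.T_max)
        assert new_state.time == pytest.approx(2.0)


class TestEstimator:
    def test_sklearn_protocol(self):
        from sklearn.base import clone

        est = AdaptiveBioheatEstimator(grid_shape=(31, 31, 31), dt=0.25)
        params = est.get_params()
        assert params["dt"] == 0.25
        est2 = clone(est)
        assert est2.get_params()["grid_shape"] == (31, 31, 31)
        est3 = est.set_params(initial_D=2.0)
        assert est3.initial_D == 2.0

    def test_fit_produces_records_and_volume(self, tiny_phantom):
        _, maps, _ = tiny_phantom
        est = AdaptiveBioheatEstimator(grid_shape=(31, 31, 31)).fit(maps)
        assert len(est.fit_records_) == len(maps)
        assert est.volume_.field.shape == (31, 31, 31)
        assert 0.1 <= est.D_ <= 5.0
        assert np.all(np.isfinite(est.volume_.field))
        # SSE never increases within a fit
        for r in est.fit_records_:
            if not r.skipped:
                assert r.sse_after <= r.sse_before + 1e-9

    def test_determinism_of_full_fit(self, tiny_phantom):
        _, maps, _ = tiny_phantom
        e1 = AdaptiveBioheatEstimator(grid_shape=(31, 31, 31)).fit(maps)
        e2 = AdaptiveBioheatEstimator(grid_shape=(31, 31, 31)).fit(maps)
        assert e1.D_ == e2.D_
        assert e1.T_max_ == e2.T_max_
        np.testing.assert_array_equal(e1.volume_.field, e2.volume_.field)

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            AdaptiveBioheatEstimator().predict([[0.0, 0.0, 0.0]])

    def test_unfitted_empty_series_rejected(self):
        with pytest.raises(ValueError):
            AdaptiveBioheatEstimator().fit([])
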