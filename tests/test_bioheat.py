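import numpy as np
import pytest

from adaptherm.bioheat import (
    SolverState,
    SourceProfile,
    TissueParams,
    absolute_source,
    adi_step,
    perfusion_rate,
    simulate,
    sink_term,
    source_profile,
    thomas_solve,
)
from adaptherm.geometry import SliceFrame, VolumeGrid
from adaptherm.isotherms import extract_isotherm_set
from adaptherm.phantom import analytic_gaussian_field
from adaptherm.thermometry import TemperatureMap


def make_state(n=21, spacing=1.0, dt=0.5, D=1.0, T0=20.0, **kw):
    g = VolumeGrid(shape=(n, n, n), spacing=spacing)
    g.field[:] = T0
    return SolverState(volume=g, dt=dt, boundary_T=T0,
                       params=TissueParams(D=D), **kw)


def axis_source(state, q, T_max=None):
    z = state.volume.axes[2]
    pts = np.zeros((len(z), 3))
    pts[:, 2] = z
    prof = SourceProfile(axis_points=pts, q=np.asarray(q, float), q_max=1.0)
    return absolute_source(prof, T_max) if T_max is not None else prof


class TestSourceProfile:
    def test_single_axis_point_self_normalises(self, ridge_map):
        iso_set = extract_isotherm_set(ridge_map, [50.0])
        prof = source_profile([[0.0, 0.0, 0.0]], [iso_set], [ridge_map.frame])
        assert prof.q[0] == pytest.approx(1.0)

    def test_hand_computed_relative_strengths(self):
        # axis points with summed orthogonal distances {10, 20, 5} mm must
        # get relative strengths {0.5, 1.0, 0.25}; isotherms are built
        # directly so the distances are exact
        from adaptherm.isotherms import Isotherm, IsothermSet

        frame = SliceFrame(angle=0.0, matrix=(3, 41), pixel_spacing=1.0)
        radii = [10, 20, 5]
        vertices = np.array([[r, 20 + radii[r]] for r in range(3)])
        iso = Isotherm(isovalue=50.0, vertices=vertices, side="right",
                       total_cost=0.0, costs=np.zeros(3))
        iso_set = IsothermSet(isotherms=[iso], tmap=None)
        pts = np.array([[0.0, 0.0, -1.0], [0, 0, 0], [0, 0, 1.0]])
        prof = source_profile(pts, [iso_set], [frame])
        np.testing.assert_allclose(prof.q, [0.5, 1.0, 0.25], atol=1e-12)
        assert prof.q_max == pytest.approx(20.0)

    def test_equal_sums_give_all_ones(self):
        frame = SliceFrame(angle=0.0, matrix=(5, 41), pixel_spacing=1.0)
        vals = np.full((5, 41), 21.0)
        vals[:, 27] = 50.0
        vals[:, 13] = 50.0
        m = TemperatureMap(vals, frame, baseline_T0=21.0)
        iso_set = extract_isotherm_set(m, [50.0])
        pts = np.zeros((5, 3))
        pts[:, 2] = np.arange(-2.0, 3.0)
        prof = source_profile(pts, [iso_set], [frame])
        np.testing.assert_allclose(prof.q, 1.0)

    def test_empty_isotherms_raise(self):
        with pytest.raises(ValueError):
            source_profile([[0, 0, 0]], [], [])


class TestAbsoluteSource:
    def test_scaling(self):
        prof = SourceProfile(axis_points=[[0, 0, 0], [0, 0, 1], [0, 0, 2]],
                             q=[1.0, 0.5, 0.0], q_max=1.0)
        out = absolute_source(prof, 300.0)
        np.testing.assert_allclose(out.T_abs, [300.0, 150.0, 0.0])

    def test_sub_baseline_values_floored_on_application(self):
        state = make_state(n=15, T0=20.0)
        state.source = axis_source(state, [0.0] * 7 + [1.0] + [0.0] * 7,
                                   T_max=10.0)  # T_i = 10 < baseline
        out = adi_step(state)
        assert out.volume.field.min() >= 20.0 - 1e-9


class TestPerfusionRate:
    def test_hand_evaluation(self):
        w = perfusion_rate(1e-6, 5e-3, 0.1)
        assert w == pytest.approx(1e-3 / (np.pi * 2.5e-5 * 0.1), rel=1e-12)
        assert w == pytest.approx(127.32, abs=0.01)

    def test_zero_flow_and_linearity(self):
        assert perfusion_rate(0.0, 5e-3, 0.1) == 0.0
        assert perfusion_rate(2e-6, 5e-3, 0.1) == pytest.approx(
            2 * perfusion_rate(1e-6, 5e-3, 0.1))

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            perfusion_rate(1e-6, 0.0, 0.1)


class TestSinkTerm:
    def test_zero_without_perfusion(self):
        state = make_state()
        np.testing.assert_array_equal(sink_term(state), 0.0)

    def test_equilibrium_at_arterial_temperature(self):
        state = make_state(T0=25.0)
        state.params.w_b = 100.0
        state.sink_mask = np.zeros(state.volume.shape, bool)
        state.sink_mask[10, 10, :] = True
        np.testing.assert_allclose(sink_term(state), 0.0)

    def test_hand_evaluated_magnitude(self):
        state = make_state(T0=60.0)
        state.params = TissueParams(D=1.0, w_b=127.32, c_b=4182.0,
                                    rho_c=4e6, T_a=25.0)
        state.sink_mask = np.ones(state.volume.shape, bool)
        p = sink_term(state)
        assert p[10, 10, 10] == pytest.approx(
            127.32 * 4182.0 * (25.0 - 60.0) / 4e6, rel=1e-12)
        assert p[10, 10, 10] == pytest.approx(-4.659, abs=0.01)

    def test_perfusion_without_mask_is_config_error(self):
        state = make_state()
        state.params.w_b = 10.0
        with pytest.raises(ValueError):
            sink_term(state)


class TestThomasSolve:
    def test_identity_system(self):
        rhs = np.array([1.0, 2.0, 3.0])
        x = thomas_solve(np.zeros(3), np.ones(3), np.zeros(3), rhs)
        np.testing.assert_allclose(x, rhs)

    def test_small_system_matches_dense(self):
        lower = np.array([0.0, 1.0, 1.0])
        diag = np.array([2.0, 2.0, 2.0])
        upper = np.array([1.0, 1.0, 0.0])
        rhs = np.array([1.0, 2.0, 3.0])
        a = np.diag(diag) + np.diag(lower[1:], -1) + np.diag(upper[:-1], 1)
        np.testing.assert_allclose(thomas_solve(lower, diag, upper, rhs),
                                   np.linalg.solve(a, rhs), atol=1e-12)

    @pytest.mark.parametrize("n", [5, 50, 500])
    def test_random_diagonally_dominant_vs_dense(self, n):
        rng = np.random.default_rng(n)
        lower = rng.uniform(-1, 1, n)
        upper = rng.uniform(-1, 1, n)
        diag = 2.5 + rng.uniform(0, 1, n)
        rhs = rng.normal(size=n)
        a = np.diag(diag) + np.diag(lower[1:], -1) + np.diag(upper[:-1], 1)
        x = thomas_solve(lower, diag, upper, rhs)
        assert np.max(np.abs(x - np.linalg.solve(a, rhs))) < 1e-10

    def test_batched_systems(self):
        rng = np.random.default_rng(7)
        lower = rng.uniform(-1, 1, (4, 9))
        upper = rng.uniform(-1, 1, (4, 9))
        diag = 3.0 + rng.uniform(0, 1, (4, 9))
        rhs = rng.normal(size=(4, 9))
        x = thomas_solve(lower, diag, upper, rhs)
        for k in range(4):
            a = (np.diag(diag[k]) + np.diag(lower[k, 1:], -1)
                 + np.diag(upper[k, :-1], 1))
            np.testing.assert_allclose(x[k], np.linalg.solve(a, rhs[k]),
                                       atol=1e-10)

    def test_zero_pivot_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            thomas_solve(np.zeros(3), np.zeros(3), np.zeros(3), np.ones(3))


class TestAdiStep:
    def test_uniform_field_is_fixed_point(self):
        state = make_state(T0=25.0)
        out = simulate(state, 5.0)
        np.testing.assert_allclose(out.volume.field, 25.0, atol=1e-9)

    def test_gaussian_matches_analytic_kernel(self):
        D = 1.0
        g = VolumeGrid(shape=(41, 41, 41), spacing=1.0)
        g.field = analytic_gaussian_field(0.0, D, 30.0, 4.0, 20.0, g)
        state = SolverState(volume=g, dt=0.25, boundary_T=20.0,
                            params=TissueParams(D=D))
        out = simulate(state, 2.0)
        ref = analytic_gaussian_field(out.time, D, 30.0, 4.0, 20.0, g)
        assert np.max(np.abs(out.volume.field - ref)) < 0.1

    def test_second_order_convergence(self):
        D = 1.0

        def err(n, dt):
            spacing = 40.0 / (n - 1)
            g = VolumeGrid(shape=(n, n, n), spacing=spacing)
            g.field = analytic_gaussian_field(0.0, D, 30.0, 4.0, 20.0, g)
            st = SolverState(volume=g, dt=dt, boundary_T=20.0,
                             params=TissueParams(D=D))
            st = simulate(st, 2.0)
            ref = analytic_gaussian_field(st.time, D, 30.0, 4.0, 20.0, g)
            return np.max(np.abs(st.volume.field - ref))

        e1, e2 = err(21, 0.5), err(41, 0.25)
        order = np.log2(e1 / e2)
        assert 1.7 <= order <= 2.3

    @pytest.mark.parametrize("dt", [0.1, 1.0, 10.0])
    def test_unconditional_stability_with_fast_diffusion(self, dt):
        state = make_state(n=25, dt=dt, D=5.0, T0=20.0)
        state.source = axis_source(state, [1.0] * 25, T_max=150.0)
        out = simulate(state, 10 * dt)
        f = out.volume.field
        assert np.all(np.isfinite(f))
        assert f.min() >= 20.0 - 1e-6 and f.max() <= 150.0 + 1e-6

    def test_maximum_principle_without_source(self):
        # Crank-Nicolson obeys the discrete maximum principle at moderate
        # Courant number (it is A-stable, not L-stable, so arbitrarily
        # rough data at huge dt may transiently over/undershoot)
        rng = np.random.default_rng(5)
        state = make_state(n=15, dt=0.25, D=1.0, T0=20.0)
        state.volume.field = 20.0 + rng.uniform(0, 30, (15, 15, 15))
        lo, hi = state.volume.field.min(), state.volume.field.max()
        out = simulate(state, 20.0)
        assert out.volume.field.min() >= min(lo, 20.0) - 1e-9
        assert out.volume.field.max() <= hi + 1e-9

    def test_symmetric_source_gives_symmetric_field(self):
        state = make_state(n=21)
        q = np.exp(-np.linspace(-2, 2, 21) ** 2)
        state.source = axis_source(state, q, T_max=120.0)
        out = simulate(state, 10.0)
        f = out.volume.field
        # reflection symmetry about the axis is exact ...
        assert np.max(np.abs(f - f[::-1, :, :])) < 1e-9
        assert np.max(np.abs(f - f[:, ::-1, :])) < 1e-9
        # ... x<->y exchange only up to the directional splitting error
        assert np.max(np.abs(f - np.swapaxes(f, 0, 1))) < 0.1

    def test_nonfinite_field_rejected(self):
        state = make_state(n=9)
        state.volume.field[4, 4, 4] = np.nan
        with pytest.raises(FloatingPointError):
            adi_step(state)


class TestSimulate:
    def test_zero_duration_is_identity(self):
        state = make_state()
        out = simulate(state, 0.0)
        np.testing.assert_array_equal(out.volume.field, state.volume.field)
        assert out.time == state.time

    def test_composition(self):
        state = make_state(n=15)
        state.source = axis_source(state, [1.0] * 15, T_max=100.0)
        once = simulate(state, 4.0)
        twice = simulate(simulate(state, 2.0), 2.0)
        np.testing.assert_allclose(once.volume.field, twice.volume.field,
                                   atol=1e-12)

    def test_steady_state_monotone_radial_decay(self):
        state = make_state(n=21, dt=1.0)
        state.source = axis_source(state, [1.0] * 21, T_max=100.0)
        out = simulate(state, 200.0)
        mid = out.volume.field[10, 10:, 10]
        assert np.all(np.diff(mid) <= 1e-9)
        assert mid[0] == pytest.approx(100.0, abs=1e-3)
        assert mid[-1] == pytest.approx(20.0)

    def test_heat_sink_cools_tube_region(self):
        base = make_state(n=21, dt=0.5)
        base.source = axis_source(base, [1.0] * 21, T_max=120.0)
        hot = simulate(base, 40.0)

        sink = base.copy()
        mask = np.zeros(sink.volume.shape, bool)
        mask[15:18, 9:12, :] = True
        sink.sink_mask = mask
        sink.params = TissueParams(D=1.0, w_b=127.0, T_a=20.0)
        cold = simulate(sink, 40.0)
        assert (cold.volume.field[mask].mean()
                < hot.volume.field[mask].mean() - 1.0)
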