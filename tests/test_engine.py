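"""Euler pressure engine against closed-form oracles."""

import numpy as np
import pytest

from ivpglab import engine
from ivpglab.engine import PA_PER_MMHG, RHO_BLOOD
from ivpglab.io import VelocityMap


def make_map(values, lv_length_cm=2.0, duration_ms=100.0, **kw):
    values = np.asarray(values, dtype=float)
    n_s, n_t = values.shape
    return VelocityMap(
        values=values,
        ds=lv_length_cm / (n_s - 1),
        dt=duration_ms / (n_t - 1),
        lv_length=lv_length_cm,
        **kw,
    )


def uniform_acceleration_map(a=5.0, n_s=64, n_t=256, lv_length_cm=2.0, duration_ms=100.0):
    """v(s, t) = a * t, no spatial variation (a in m/s^2, t in s)."""
    t_s = np.linspace(0.0, duration_ms / 1000.0, n_t)
    return make_map(
        np.broadcast_to(a * t_s, (n_s, n_t)).copy(),
        lv_length_cm=lv_length_cm,
        duration_ms=duration_ms,
    )


def traveling_sine_map(n_s, n_t, V=0.8, lv_length_cm=2.0, duration_ms=100.0,
                       wavelength_cm=4.0, period_ms=50.0):
    L_m = lv_length_cm / 100.0
    s = np.linspace(0.0, L_m, n_s)[:, None]
    t = np.linspace(0.0, duration_ms / 1000.0, n_t)[None, :]
    k = 2.0 * np.pi / (wavelength_cm / 100.0)
    w = 2.0 * np.pi / (period_ms / 1000.0)
    vmap = make_map(V * np.sin(w * t - k * s), lv_length_cm, duration_ms)
    return vmap, V, k, w


def sine_ivpd_closed_form(V, k, w, L_m, t_s):
    """IVPD(t) in Pa: rho * [ (V w / k)(sin(wt) - sin(wt - kL)) + (v(L)^2 - v(0)^2)/2 ]."""
    inertial = (V * w / k) * (np.sin(w * t_s) - np.sin(w * t_s - k * L_m))
    v0 = V * np.sin(w * t_s)
    vL = V * np.sin(w * t_s - k * L_m)
    return RHO_BLOOD * (inertial + 0.5 * (vL**2 - v0**2))


class TestPressureGradientField:
    def test_constant_velocity_gives_zero_field(self):
        vmap = make_map(np.full((8, 12), 0.7))
        assert np.allclose(engine.pressure_gradient_field(vmap), 0.0)

    def test_uniform_acceleration_closed_form(self):
        # v = a t with a = 5 m/s^2: dP/ds = -rho a = -5300 Pa/m everywhere
        vmap = uniform_acceleration_map(a=5.0)
        field = engine.pressure_gradient_field(vmap)
        assert np.allclose(field, -RHO_BLOOD * 5.0, rtol=1e-10)

    def test_traveling_sine_matches_symbolic_gradient(self):
        vmap, V, k, w = traveling_sine_map(64, 256)
        s = (vmap.s_cm / 100.0)[:, None]
        t = (vmap.t_ms / 1000.0)[None, :]
        theta = w * t - k * s
        exact = -RHO_BLOOD * (V * w * np.cos(theta) - V**2 * k * np.sin(theta) * np.cos(theta))
        field = engine.pressure_gradient_field(vmap)
        scale = np.max(np.abs(exact))
        assert np.max(np.abs(field - exact)) / scale < 0.01

    def test_non_finite_cell_is_reported(self):
        values = np.zeros((5, 5))
        values[2, 3] = np.nan
        vmap = make_map(np.ones((5, 5)))
        vmap.values[2, 3] = np.nan  # bypass constructor validation
        with pytest.raises(ValueError, match=r"row=2, col=3"):
            engine.pressure_gradient_field(vmap)

    def test_too_small_grid_rejected(self):
        vmap = make_map(np.zeros((3, 3)))
        vmap.values = vmap.values[:2]
        with pytest.raises(ValueError, match="3 samples"):
            engine.pressure_gradient_field(vmap)


class TestIvpdTrace:
    def test_constant_velocity_gives_zero_traces(self):
        trace = engine.ivpd_trace(make_map(np.full((8, 12), 0.4)))
        for arr in (trace.total, trace.basal, trace.mid_apical):
            assert np.allclose(arr, 0.0)

    def test_uniform_acceleration_total_and_basal(self):
        # IVPD = rho a L = 1060 * 5 * 0.02 = 106 Pa = 0.795 mmHg; basal = 1/3
        vmap = uniform_acceleration_map(a=5.0, n_s=61, n_t=64)  # L/3 on-grid
        trace = engine.ivpd_trace(vmap)
        expected = RHO_BLOOD * 5.0 * 0.02 / PA_PER_MMHG
        assert np.allclose(trace.total, expected, rtol=1e-9)
        assert np.allclose(trace.basal, expected / 3.0, rtol=1e-9)
        assert expected == pytest.approx(0.795, abs=5e-4)

    def test_additivity_on_generated_wave(self, cohort99):
        _, maps, _ = cohort99
        trace = engine.ivpd_trace(maps[0])
        assert np.max(np.abs(trace.total - (trace.basal + trace.mid_apical))) < 1e-9

    def test_off_grid_split_is_snapped_and_recorded(self):
        vmap = uniform_acceleration_map(n_s=64)  # L/3 falls between nodes
        trace = engine.ivpd_trace(vmap)
        assert trace.split_index == round((vmap.lv_length / 3.0) / vmap.ds)
        assert trace.split_s_cm == pytest.approx(trace.split_index * vmap.ds)

    def test_gauge_shift_changes_only_convective_term(self):
        # v = a t + b s: field = -rho (a + v b); adding c shifts it by -rho c b
        a, b, c = 5.0, 3.0, 0.25
        n_s, n_t = 16, 32
        s = np.linspace(0.0, 0.02, n_s)[:, None]
        t = np.linspace(0.0, 0.1, n_t)[None, :]
        base = make_map(a * t + b * s + 0 * (s + t))
        shifted = make_map(a * t + b * s + c + 0 * (s + t))
        diff = engine.pressure_gradient_field(shifted) - engine.pressure_gradient_field(base)
        assert np.allclose(diff, -RHO_BLOOD * c * b, rtol=1e-9)

    def test_zero_map_gives_zero_result(self):
        res = engine.compute_ivpg(make_map(np.zeros((8, 12))))
        assert res.total_ivpg == res.basal_ivpg == res.mid_apical_ivpg == 0.0


class TestConvergence:
    def test_sine_ivpd_second_order_convergence(self):
        errors = []
        for n_s, n_t in [(32, 128), (64, 256), (128, 512)]:
            vmap, V, k, w = traveling_sine_map(n_s, n_t)
            trace = engine.ivpd_trace(vmap)
            t_s = vmap.t_ms / 1000.0
            exact = sine_ivpd_closed_form(V, k, w, 0.02, t_s) / PA_PER_MMHG
            interior = slice(2, -2)
            errors.append(
                np.max(np.abs(trace.total[interior] - exact[interior]))
                / np.max(np.abs(exact))
            )
        assert errors[1] < 0.01  # within 1% at the 64 x 256 grid
        orders = [np.log2(errors[i] / errors[i + 1]) for i in range(2)]
        assert all(1.6 < o < 2.4 for o in orders)


class TestIvpgFromTrace:
    @staticmethod
    def flat_trace(total, basal, n=11, lv_length=2.0):
        times = np.arange(n, dtype=float)
        tot = np.full(n, float(total))
        bas = np.full(n, float(basal))
        return engine.IvpdTrace(
            times=times, total=tot, basal=bas, mid_apical=tot - bas,
            lv_length=lv_length,
        )

    def test_constant_trace_arithmetic(self):
        res = engine.ivpg_from_trace(self.flat_trace(4.0, 1.0, lv_length=2.0))
        assert res.total_ivpg == pytest.approx(2.0)

    def test_segments_evaluated_at_peak_instant_are_additive(self, cohort99):
        _, maps, _ = cohort99
        res = engine.compute_ivpg(maps[3])
        assert res.total_ivpg == pytest.approx(
            res.basal_ivpg + res.mid_apical_ivpg, abs=1e-12
        )

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            engine.ivpg_from_trace(self.flat_trace(4.0, 1.0), filling_window=(8.0, 2.0))

    def test_multi_cycle_average_equals_single_cycle_for_periodic_map(self, cohort99):
        _, maps, _ = cohort99
        vmap = maps[0]
        res = engine.compute_ivpg(vmap)
        assert res.n_cycles == 2
        assert res.per_cycle_total[0] == pytest.approx(res.per_cycle_total[1], rel=1e-9)

    def test_amplitude_monotonicity(self):
        from ivpglab import synthetic
        cfg = synthetic.SimConfig()
        truth = synthetic.mean_truth_for_hr(cfg, 300.0)
        totals = []
        for scale in (1.0, 2.0):
            import dataclasses
            t = dataclasses.replace(truth, e_amplitude=truth.e_amplitude * scale)
            totals.append(engine.compute_ivpg(synthetic.generate_cycle(t)).total_ivpg)
        assert totals[1] > totals[0]

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            engine.ivpg_from_trace(self.flat_trace(4.0, 1.0), lv_length=-1.0)
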