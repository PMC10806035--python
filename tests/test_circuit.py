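"""Rate equations, plasticity rules, and the single-step update engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from mbsoc import CircuitParams, GRID_BOUNDS, initial_state, make_params, step
from mbsoc.circuit import (dan_rate, depress_kc_mbon_minus, kc_rates,
                           mbon_rates, potentiate_kc_dan, potentiate_kc_kc,
                           potentiate_mbon_dan)


def _state(model="basic", n_kc=2000, **kw):
    return initial_state(make_params(model, kw or None, n_kc=n_kc)
                         if model != "basic" else
                         CircuitParams("basic", n_kc=n_kc, **kw))


def _drive(active, n_kc=2000, rate=3.0):
    v = np.zeros(n_kc)
    v[:active] = rate
    return v


class TestMbonRates:
    def test_uniform_weights_give_published_rates(self):
        state = _state()
        assert mbon_rates(_drive(200), state) == (pytest.approx(49.8),
                                                  pytest.approx(49.8))
        r_plus, r_minus = mbon_rates(_drive(100), state)
        assert r_minus == pytest.approx(24.9)

    def test_zero_weights_give_zero_rate(self):
        state = _state()
        state.w_kc_mbon_minus[:] = 0.0
        assert mbon_rates(_drive(200), state)[1] == 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mbon_rates(np.zeros(10), _state())

    @settings(max_examples=30, derandomize=True)
    @given(hnp.arrays(float, 50, elements=st.floats(0, 10)),
           hnp.arrays(float, 50, elements=st.floats(0, 10)),
           st.floats(0, 5))
    def test_linearity_in_kc_rates(self, a, b, scale):
        state = _state(n_kc=50)
        pa, ma = mbon_rates(a, state)
        pb, mb = mbon_rates(b, state)
        ps, ms = mbon_rates(scale * a + b, state)
        assert ps == pytest.approx(scale * pa + pb, abs=1e-9)
        assert ms == pytest.approx(scale * ma + mb, abs=1e-9)


class TestDanRate:
    def test_basic_circuit_passes_external_input_through(self):
        p = CircuitParams("basic")
        r, ip_int = dan_rate(p, initial_state(p), 5.0, _drive(200), 49.8, 49.8)
        assert (r, ip_int) == (5.0, 0.0)

    def test_model3_naive_feedback(self):
        p = make_params("m3", {"init_mbon_plus_dan": 0.272727,
                               "init_mbon_minus_dan": 0.262626,
                               "alpha_kc_mbon_minus": 0.003121,
                               "dan_activation": 5.0})
        r, _ = dan_rate(p, initial_state(p), 5.0, _drive(200), 49.8, 49.8)
        assert r == pytest.approx(5.503, abs=1e-3)

    def test_model4_tonic_minus_inhibition(self):
        p = make_params("m4", {"init_mbon_minus_dan": 0.131313,
                               "alpha_kc_mbon_minus": 0.003182,
                               "r_dan_baseline": 11.212121,
                               "dan_activation": 3.727273})
        r, _ = dan_rate(p, initial_state(p), 3.727273, _drive(200), 49.8, 49.8)
        assert r == pytest.approx(8.400, abs=1e-3)

    def test_model2_naive_feedforward(self):
        p = make_params("m2", {"init_kc_dan": 0.000505,
                               "alpha_kc_mbon_minus": 0.003333,
                               "alpha_kc_dan": 0.000677,
                               "dan_activation": 5.727273})
        r, _ = dan_rate(p, initial_state(p), 5.727273, _drive(200), 49.8, 49.8)
        assert r == pytest.approx(6.030, abs=1e-3)

    def test_strong_inhibition_is_rectified_at_zero(self):
        p = make_params("m4", {"init_mbon_minus_dan": 0.5,
                               "alpha_kc_mbon_minus": 0.001,
                               "r_dan_baseline": 0.0, "dan_activation": 1.0})
        r, ip_int = dan_rate(p, initial_state(p), 0.0, _drive(200), 49.8, 49.8)
        assert r == 0.0 and ip_int < 0


class TestPlasticityRules:
    def test_depression_step_matches_worked_value(self):
        state = _state()
        depress_kc_mbon_minus(state, _drive(200), 8.400, 0.003182)
        assert state.w_kc_mbon_minus[0] == pytest.approx(0.056271, abs=1e-6)
        # inactive synapses untouched, plus pathway untouched
        assert state.w_kc_mbon_minus[200] == 0.083
        assert (state.w_kc_mbon_plus == 0.083).all()

    def test_depression_clamps_at_zero(self):
        state = _state()
        state.w_kc_mbon_minus[:] = 0.0294
        depress_kc_mbon_minus(state, _drive(200), r_dan=1.0, alpha=0.0398)
        assert (state.w_kc_mbon_minus[:200] == 0.0).all()

    @settings(max_examples=30, derandomize=True)
    @given(hnp.arrays(float, 40, elements=st.floats(0, 0.2)),
           hnp.arrays(float, 40, elements=st.floats(0, 5)),
           st.floats(0, 20), st.floats(0, 0.01))
    def test_depression_equals_elementwise_loop_oracle(self, w, kc, r_dan, alpha):
        expected = np.array([max(0.0, wi - alpha * r_dan) if ki > 0 else wi
                             for wi, ki in zip(w, kc)])
        state = _state(n_kc=40)
        state.w_kc_mbon_minus[:] = w
        depress_kc_mbon_minus(state, kc, r_dan, alpha)
        assert np.allclose(state.w_kc_mbon_minus, expected, atol=1e-15)

    def test_kc_kc_potentiation_increments_coactive_pairs_only(self):
        state = _state("m1", n_kc=2000, init_kc_dan=0.001,
                       alpha_kc_mbon_minus=0.004, alpha_kc_kc=0.000162,
                       dan_activation=7.272727)
        potentiate_kc_kc(state, _drive(200), 0.000162)
        assert np.allclose(state.w_kc_kc[:200, :200], 0.000162)
        assert not state.w_kc_kc[200:, :].any()
        assert not state.w_kc_kc[:200, 200:].any()
        potentiate_kc_kc(state, np.zeros(2000), 0.000162)  # no active cells
        assert np.allclose(state.w_kc_kc[:200, :200], 0.000162)

    def test_kc_dan_potentiation_gated_by_dan_and_activity(self):
        state = _state("m2", n_kc=2000, init_kc_dan=0.000505,
                       alpha_kc_mbon_minus=0.003333, alpha_kc_dan=0.000677,
                       dan_activation=5.727273)
        potentiate_kc_dan(state, _drive(200), 6.030, 0.000677)
        assert state.w_kc_dan[0] == pytest.approx(0.004587, abs=1e-6)
        assert state.w_kc_dan[500] == pytest.approx(0.000505)
        before = state.w_kc_dan.copy()
        potentiate_kc_dan(state, _drive(200), 0.0, 0.000677)  # silent DAN
        assert np.array_equal(state.w_kc_dan, before)

    def test_mbon_dan_potentiation_needs_coincidence(self):
        state = _state("m5", n_kc=2000, init_mbon_plus_dan=0.080808,
                       alpha_kc_mbon_minus=0.003182,
                       alpha_mbon_plus_dan=0.003, dan_activation=4.727273)
        potentiate_mbon_dan(state, 49.8, 8.751, 0.003)
        assert state.w_mbon_plus_dan == pytest.approx(0.107061, abs=1e-5)
        potentiate_mbon_dan(state, 0.0, 8.751, 0.003)  # silent MBON+
        assert state.w_mbon_plus_dan == pytest.approx(0.107061, abs=1e-5)


class TestModel1Recurrence:
    def test_zero_recurrence_returns_the_drive(self):
        p = make_params("m1", {"init_kc_dan": 0.001, "alpha_kc_mbon_minus": 0.004,
                               "alpha_kc_kc": 0.000162, "dan_activation": 7.272727})
        state = initial_state(p)
        drive = _drive(100)
        assert np.array_equal(kc_rates(p, state, drive), drive)

    def test_one_pass_propagation_onto_a_silent_cell(self):
        p = make_params("m1", {"init_kc_dan": 0.001, "alpha_kc_mbon_minus": 0.004,
                               "alpha_kc_kc": 0.000162, "dan_activation": 7.272727})
        state = initial_state(p)
        state.w_kc_kc[:100, 1999] = 0.01  # 100 driven cells onto one silent cell
        r = kc_rates(p, state, _drive(100))
        assert r[1999] == pytest.approx(100 * 3.0 * 0.01)  # 3.0 Hz
        assert np.array_equal(r[:100], np.full(100, 3.0))


class TestStep:
    def test_plasticity_off_leaves_state_untouched(self, optima):
        for model, combo in optima.items():
            p = make_params(model, combo)
            state = initial_state(p)
            before = state.copy()
            out = step(p, state, _drive(200), reward_on=True, plasticity_on=False)
            assert out.r_mbon_plus == pytest.approx(49.8)
            assert np.array_equal(state.w_kc_mbon_minus, before.w_kc_mbon_minus)
            assert state.w_mbon_plus_dan == before.w_mbon_plus_dan

    def test_basic_rewarded_step_depresses_by_alpha_times_dan(self):
        p = CircuitParams("basic", alpha_kc_mbon_minus=0.003, dan_activation=5.0)
        state = initial_state(p)
        out = step(p, state, _drive(200), reward_on=True, plasticity_on=True)
        assert out.r_dan == 5.0
        assert state.w_kc_mbon_minus[0] == pytest.approx(0.083 - 0.003 * 5.0)

    def test_model4_foc_dan_trajectory(self, optima):
        p = make_params("m4", optima["m4"])
        state = initial_state(p)
        dans = [step(p, state, _drive(200), True, True).r_dan for _ in range(3)]
        assert dans == pytest.approx([8.400, 10.506, 13.140], abs=1e-3)

    @pytest.mark.parametrize("model", ["m1", "m2", "m3", "m4", "m5"])
    def test_zeroed_extensions_reduce_to_the_basic_circuit(self, model):
        """Each motif with its extension weights/rates at 0 follows the basic
        trajectory step for step."""
        shared = {"alpha_kc_mbon_minus": 0.002, "dan_activation": 6.0}
        ext = make_params(model, dict(shared), n_kc=400)
        basic = CircuitParams("basic", n_kc=400, **shared)
        s_ext, s_basic = initial_state(ext), initial_state(basic)
        drive = _drive(40, n_kc=400)
        for reward in (True, True, False, True):
            o1 = step(ext, s_ext, drive, reward, True)
            o2 = step(basic, s_basic, drive, reward, True)
            assert o1.r_dan == pytest.approx(o2.r_dan, abs=1e-12)
            assert o1.r_mbon_minus == pytest.approx(o2.r_mbon_minus, abs=1e-12)
            assert np.allclose(s_ext.w_kc_mbon_minus, s_basic.w_kc_mbon_minus)

    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(st.sampled_from(["m2", "m3", "m4", "m5"]),
           st.lists(st.tuples(st.booleans(), st.integers(0, 3)), min_size=1,
                    max_size=6),
           st.integers(0, 100))
    def test_weights_and_rates_stay_non_negative(self, model, schedule, seed):
        rng = np.random.default_rng(seed)
        combo = {n: float(rng.uniform(lo, hi))
                 for n, (lo, hi) in GRID_BOUNDS[model].items()}
        p = make_params(model, combo, n_kc=200)
        state = initial_state(p)
        for reward, stim in schedule:
            drive = np.zeros(200)
            drive[stim * 40:(stim + 1) * 40] = 3.0
            out = step(p, state, drive, reward, True)
            assert out.r_dan >= 0 and out.r_mbon_plus >= 0 and out.r_mbon_minus >= 0
            assert (state.w_kc_mbon_minus >= 0).all()
            assert state.w_mbon_plus_dan >= 0 and state.w_mbon_minus_dan >= 0
        # MBON+ is never plastic: rate for a fixed stimulus is unchanged
        probe = np.zeros(200); probe[:40] = 3.0
        assert step(p, state, probe, False, False).r_mbon_plus == pytest.approx(
            40 * 3.0 * 0.083)
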