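import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grn_softmem.reservoir import build_reservoir
from grn_softmem.synth import delay_chain
from grn_softmem.tasks import (
    TaskProtocol,
    critical_memory_capacity,
    delayed_and_target,
    delayed_and_task,
    kstar_from_profile,
    memory_capacity_at_k,
    memory_capacity_profile,
    memory_coefficient,
    narma10_response,
    narma10_series,
    narma10_task,
    paired_pulse_inputs,
    pulse_train,
)


class TestMemoryCoefficient:
    def test_perfect_recall_scores_one(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(-1, 1, 500)
        assert memory_coefficient(u, u) == pytest.approx(1.0)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        u = rng.uniform(-1, 1, 500)
        assert memory_coefficient(3.2 * u - 0.7, u) == pytest.approx(1.0)

    def test_independent_series_score_near_zero(self):
        rng = np.random.default_rng(2)
        mc = memory_coefficient(rng.uniform(-1, 1, 1000), rng.uniform(-1, 1, 1000))
        assert mc < 0.05

    def test_degenerate_output_scores_zero_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert memory_coefficient(np.ones(50), np.arange(50.0)) == 0.0


class TestMemoryCapacity:
    def test_scores_lie_in_unit_interval(self, surrogate_reservoir):
        profile = memory_capacity_profile(
            surrogate_reservoir, k_max=20, protocol=TaskProtocol(seed=3)
        )
        assert np.all(profile >= 0.0) and np.all(profile <= 1.0)

    def test_delay_line_remembers_up_to_its_length(self):
        """A delay chain driven at its head recalls inputs over roughly its
        own length."""
        sys = build_reservoir(
            delay_chain(10), rho=0.9, n_inputs=1, seed=1, input_nodes=["v1"]
        )
        profile = memory_capacity_profile(sys, k_max=12, protocol=TaskProtocol(seed=4))
        assert np.all(profile[:5] > 0.5)

    def test_at_k_matches_profile(self, surrogate_reservoir):
        proto = TaskProtocol(seed=5)
        profile = memory_capacity_profile(surrogate_reservoir, k_max=3, protocol=proto)
        single = memory_capacity_at_k(surrogate_reservoir, 3, protocol=proto)
        assert single.score == pytest.approx(profile[2])

    def test_invalid_delay(self, surrogate_reservoir):
        with pytest.raises(ValueError):
            memory_capacity_at_k(surrogate_reservoir, 0)


class TestKstar:
    def test_largest_crossing_not_first(self):
        profile = [0.9, 0.8, 0.6, 0.4, 0.7, 0.3]
        assert kstar_from_profile(profile) == 5
        assert kstar_from_profile(profile, first_crossing=True) == 3

    def test_all_below_threshold(self):
        assert kstar_from_profile([0.4, 0.3, 0.2]) == 0

    def test_task_result_fields(self, surrogate_reservoir):
        res = critical_memory_capacity(
            surrogate_reservoir, k_max=5, protocol=TaskProtocol(seed=6)
        )
        assert res.task == "critical_memory_capacity"
        assert res.score == int(res.score) and 0 <= res.score <= 5


class TestNarma10:
    def test_zero_input_hand_trace(self):
        y = narma10_response(np.zeros(50))
        assert y[0] == 0.0
        assert y[1] == pytest.approx(0.1)
        assert y[2] == pytest.approx(0.1305)

    def test_zero_input_fixed_point(self):
        """y = 0.3y + 0.5y^2 + 0.1 has stable root 0.7 - sqrt(0.29)."""
        y = narma10_response(np.zeros(3000))
        assert y[-1] == pytest.approx(0.7 - np.sqrt(0.29), abs=1e-9)

    def test_series_deterministic(self):
        s1, y1 = narma10_series(500, seed=11)
        s2, y2 = narma10_series(500, seed=11)
        assert np.array_equal(s1, s2) and np.array_equal(y1, y2)

    def test_inputs_in_range(self):
        s, y = narma10_series(500, seed=12)
        assert np.all((s >= 0.0) & (s < 0.5))
        assert np.all(np.abs(y) <= 10.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            narma10_series(5, seed=0)

    def test_task_beats_mean_predictor_on_surrogate(self, surrogate_reservoir):
        res = narma10_task(surrogate_reservoir, TaskProtocol(seed=13))
        assert 0.0 < res.score < 1.0


class TestPulseTrain:
    def test_zero_rate_gives_silence(self):
        assert np.all(pulse_train(600, rate=0.0, seed=0) == 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_runs_have_exact_duration(self, seed):
        x = pulse_train(600, pulse_duration=3, rate=0.05, seed=seed)
        padded = np.concatenate([[0.0], x, [0.0]])
        starts = np.flatnonzero(np.diff(padded) > 0.5)
        ends = np.flatnonzero(np.diff(padded) < -0.5)
        assert np.all(ends - starts == 3)

    def test_expected_pulse_count(self):
        counts = [
            np.count_nonzero(np.diff(np.concatenate([[0.0], pulse_train(600, seed=s)])) > 0.5)
            for s in range(200)
        ]
        assert 6 <= np.mean(counts) <= 14

    def test_refractory_gap(self):
        x = pulse_train(2000, pulse_duration=3, rate=0.2, seed=1)
        onsets = np.flatnonzero(np.diff(np.concatenate([[0.0], x])) > 0.5)
        assert np.all(np.diff(onsets) >= 9)


class TestDelayedAndTarget:
    def test_pulse_coincidence(self):
        I1 = np.zeros(30)
        I2 = np.zeros(30)
        I1[10:13] = 1.0
        I2[16:19] = 1.0
        target = delayed_and_target(I1, I2, k=6)
        assert np.all(target[16:19] == 1.0)
        assert target.sum() == 3

    def test_silent_second_input(self):
        I1 = pulse_train(100, seed=3)
        assert np.all(delayed_and_target(I1, np.zeros(100), k=6) == 0.0)

    def test_zero_delay_is_elementwise_and(self):
        I1 = np.array([1.0, 0, 1, 1])
        I2 = np.array([1.0, 1, 0, 1])
        assert np.array_equal(delayed_and_target(I1, I2, 0), [1.0, 0, 0, 1])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(0, 12))
    def test_matches_double_loop_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        I1 = (rng.random(40) < 0.3).astype(float)
        I2 = (rng.random(40) < 0.3).astype(float)
        expected = np.zeros(40)
        for t in range(40):
            if t - k >= 0 and I1[t - k] == 1.0 and I2[t] == 1.0:
                expected[t] = 1.0
        assert np.array_equal(delayed_and_target(I1, I2, k), expected)


class TestDelayedAndTask:
    def test_planted_coincidences_create_both_classes(self):
        rng = np.random.default_rng(17)
        I1, I2 = paired_pulse_inputs(600, k=6, rng=rng)
        target = delayed_and_target(I1, I2, 6)
        assert target.sum() >= 3
        assert I2.sum() > target.sum()  # non-coincident I2 pulses exist

    def test_all_zero_prediction_nrmse_closed_form(self):
        """NRMSE of silence against a binary target with fraction p of ones
        is 1/sqrt(1-p)."""
        from grn_softmem.readout import nrmse

        target = np.zeros(200)
        target[:20] = 1.0
        p = 0.1
        assert nrmse(np.zeros(200), target) == pytest.approx(1 / np.sqrt(1 - p))

    def test_surrogate_detects_coincidences(self, surrogate):
        sys = build_reservoir(surrogate, rho=0.95, n_inputs=2, seed=2)
        res = delayed_and_task(sys, TaskProtocol(series_length=600, seed=18))
        assert res.task == "delayed_and"
        assert res.score < 1.0

    def test_requires_two_inputs(self, surrogate_reservoir):
        with pytest.raises(ValueError, match="two input"):
            delayed_and_task(surrogate_reservoir)
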