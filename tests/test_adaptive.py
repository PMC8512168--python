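"""Adaptive procedures: payoff matrices, staircases, and the repetition policy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bearsim.adaptive import (
    AcalosConfig, HintConfig, SIAM_PRESETS, SiamConfig, TrialRecord,
    TwoAfcConfig, estimate_threshold, repetition_policy,
    run_2afc_frequency_track, run_acalos_track, run_hint, run_siam_track,
    siam_deltas,
)


class TestSiamDeltas:
    def test_target_08_gives_miss_4_false_alarm_5(self):
        hit, miss, fa, cr = siam_deltas(0.8)
        assert hit == -1.0
        assert miss == pytest.approx(4.0)
        assert fa == pytest.approx(5.0)
        assert cr == 0.0

    def test_target_05_doubles_on_false_alarm(self):
        hit, miss, fa, cr = siam_deltas(0.5)
        assert miss == pytest.approx(1.0)   # 1-up/1-down behavior
        assert fa == pytest.approx(2.0)     # the step size becomes double

    @pytest.mark.parametrize("t", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_target_rejected(self, t):
        with pytest.raises(ValueError):
            siam_deltas(t)

    @given(st.floats(min_value=0.05, max_value=0.95))
    @settings(max_examples=25, deadline=None)
    def test_zero_drift_at_target(self, t):
        # at the targeted hit probability the expected signal-trial step
        # vanishes: t*(-1) + (1-t)*(t/(1-t)) == 0
        hit, miss, _, _ = siam_deltas(t)
        assert t * hit + (1 - t) * miss == pytest.approx(0.0, abs=1e-9)


class TestEstimateThreshold:
    def test_mean_of_selected_reversals(self):
        assert estimate_threshold([80, 60, 74, 66, 72, 68], 2, 4) == pytest.approx(70.0)

    def test_constant_reversals(self):
        assert estimate_threshold([55.0] * 6, 2, 4) == pytest.approx(55.0)

    def test_discard_four_average_two(self):
        # the high-frequency audiometry policy
        revs = [1, 2, 3, 4, 10, 12]
        assert estimate_threshold(revs, 4, 2) == pytest.approx(11.0)

    def test_insufficient_reversals(self):
        with pytest.raises(ValueError):
            estimate_threshold([70, 71], 2, 4)


def step_observer(threshold):
    """Deterministic observer: yes iff the value is at/above threshold."""

    def respond(present, value, rng):
        if not present:
            return False
        return value >= threshold

    return respond


class TestSiamTrack:
    def test_deterministic_observer_brackets_threshold(self):
        config = SiamConfig(initial_value=90.0, step_schedule=(8.0, 4.0, 2.0),
                            bounds=(0.0, 120.0))
        track = run_siam_track(step_observer(63.0), config, seed=0)
        assert track.valid
        final_step = config.step_schedule[-1]
        assert abs(track.threshold_estimate - 63.0) <= 2 * final_step

    def test_always_yes_observer_invalidates(self):
        config = SiamConfig(initial_value=50.0, bounds=(0.0, 120.0))
        track = run_siam_track(lambda p, v, r: True, config, seed=0)
        assert not track.valid
        assert track.invalid_reason == "bounds_hit"
        assert track.threshold_estimate is None

    def test_bit_reproducible(self):
        config = SIAM_PRESETS["eAUD-N"]

        def noisy(present, value, rng):
            if not present:
                return rng.random() < 0.05
            return rng.random() < 1 / (1 + np.exp(-(value - 70) / 2))

        a = run_siam_track(noisy, config, seed=42)
        b = run_siam_track(noisy, config, seed=42)
        assert a == b

    def test_trial_outcomes_consistent(self):
        track = run_siam_track(step_observer(60.0),
                               SiamConfig(initial_value=80.0), seed=1)
        for t in track.trials:
            if t.stimulus_present:
                assert t.outcome in ("hit", "miss")
            else:
                assert t.outcome in ("false_alarm", "correct_rejection")

    def test_trial_record_rejects_inconsistent_outcome(self):
        with pytest.raises(ValueError):
            TrialRecord(0, True, 50.0, True, "miss", 0.0, False)


class TestTwoAfcTrack:
    def test_hard_limit_recovered_within_sixth_octave(self):
        fstar = 900.0

        def detect(freq, rng):
            # detection report: positive below the limit, never above
            return freq < fstar

        errors = []
        for seed in range(50):
            track = run_2afc_frequency_track(detect, TwoAfcConfig(), seed=seed)
            assert track.valid
            errors.append(np.log2(track.threshold_estimate / fstar))
        assert abs(np.mean(errors)) <= 1 / 6

    def test_chance_observer_is_noisier_than_informed(self):
        def chance(freq, rng):
            return rng.random() < 0.5

        def informed(freq, rng):
            return freq < 750.0

        est_c, est_i = [], []
        for seed in range(30):
            tc = run_2afc_frequency_track(chance, TwoAfcConfig(), seed=seed)
            ti = run_2afc_frequency_track(informed, TwoAfcConfig(), seed=seed)
            if tc.valid:
                est_c.append(np.log2(tc.threshold_estimate))
            if ti.valid:
                est_i.append(np.log2(ti.threshold_estimate))
        assert np.var(est_c) > 4 * np.var(est_i)

    def test_perfect_below_1khz_lands_near_1khz(self):
        def obs(freq, rng):
            return freq < 1000.0

        ests = []
        for seed in range(30):
            track = run_2afc_frequency_track(
                obs, TwoAfcConfig(initial_freq=500.0), seed=seed)
            if track.valid:
                ests.append(np.log2(track.threshold_estimate))
        assert 2 ** np.mean(ests) == pytest.approx(1000.0, rel=0.15)

    def test_steps_never_increase_after_reversal(self):
        def obs(freq, rng):
            return rng.random() < (0.9 if freq < 800 else 0.1)

        track = run_2afc_frequency_track(obs, TwoAfcConfig(), seed=3)
        steps = [abs(t.step_applied) for t in track.trials]
        rev_idx = [i for i, t in enumerate(track.trials) if t.reversal_flag]
        for i, j in zip(rev_idx, rev_idx[1:]):
            assert steps[j] <= steps[i] + 1e-12


class TestAcalos:
    @staticmethod
    def linear_observer(level, rng):
        return float(np.clip(0.5 * (level - 20.0), 0.0, 50.0))

    def test_pairs_cover_cu_range(self):
        pairs = run_acalos_track(self.linear_observer, AcalosConfig(), seed=0)
        cus = [cu for _, cu in pairs]
        assert min(cus) <= 5.0
        assert max(cus) >= 40.0

    def test_no_audible_response_below_threshold(self):
        def gated(level, rng):
            return 0.0 if level < 40.0 else float(np.clip(level - 40.0, 0, 50))

        pairs = run_acalos_track(gated, AcalosConfig(), seed=1)
        assert all(cu == 0.0 for level, cu in pairs if level < 40.0)

    def test_deaf_observer_raises(self):
        with pytest.raises(RuntimeError):
            run_acalos_track(lambda level, rng: 0.0, AcalosConfig(), seed=2)


class TestHint:
    def test_adaptive_srt_recovers_logistic_threshold(self):
        from scipy.special import expit

        def obs(snr, rng):
            return rng.random() < expit((snr - (-1.0)) / 0.8)

        ests = []
        for seed in range(50):
            track = run_hint(obs, "adaptive_srt", HintConfig(), seed=seed)
            ests.append(track.threshold_estimate)
        assert np.mean(ests) == pytest.approx(-1.0, abs=0.6)

    def test_perfect_observer_scores_100(self):
        score = run_hint(lambda snr, rng: True, "fixed_snr", HintConfig(), seed=0)
        assert score == 100.0

    def test_presented_snrs_on_step_grid(self):
        def obs(snr, rng):
            return rng.random() < 0.5

        track = run_hint(obs, "adaptive_srt", HintConfig(initial_snr=0.0),
                         seed=5)
        snrs = [t.tracked_value for t in track.trials]
        # after the initial large-step sentences every SNR sits on the
        # 2-dB grid laid down by the staircase
        assert all(abs(s / 2.0 - round(s / 2.0)) < 1e-9 for s in snrs[4:])


class TestRepetitionPolicy:
    def test_consistent_runs_accepted(self):
        decision, value = repetition_policy([70.0, 71.0])
        assert decision == "accept"
        assert value == pytest.approx(70.5)

    def test_outlier_triggers_repeat(self):
        decision, value = repetition_policy([70.0, 71.0, 95.0])
        assert decision == "repeat"
        assert value is None

    def test_invalid_runs_give_missing(self):
        assert repetition_policy([None, None]) == ("missing", None)
        assert repetition_policy([70.0, 71.0], [True, True]) == ("missing", None)

    def test_single_valid_run_is_missing(self):
        assert repetition_policy([70.0, None]) == ("missing", None)
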