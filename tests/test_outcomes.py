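"""Outcome estimation: d', psychometric and loudness fits, reduction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from bearsim.observers import LoudnessFunctionParams
from bearsim.outcomes import (
    ANALYSIS_VARIABLES, BEAR3_VARIABLES, ScreeningResponseSet,
    dprime_screening, fit_loudness_function, fit_wrs_psychometric,
    masking_release, reduce_to_bear3, score_binaural_pitch,
)


class TestDprime:
    def test_ceiling(self):
        d = dprime_screening(ScreeningResponseSet(hits=10, false_alarms=0))
        assert d == pytest.approx(3.07, abs=0.005)

    def test_floor(self):
        d = dprime_screening(ScreeningResponseSet(hits=0, false_alarms=0))
        assert d == pytest.approx(-0.31, abs=0.005)

    def test_equal_corrected_rates_give_zero(self):
        # h=5/10 and f=2.5/5 correct to the same rate
        h, f = 5, 2  # corrected: 5.5/11 = 0.5, 2.5/6 != 0.5 -> build exact case
        r = ScreeningResponseSet(hits=5, false_alarms=2, n_modulated=10, n_catch=4)
        # (5+0.5)/11 = 0.5 and (2+0.5)/5 = 0.5
        assert dprime_screening(r) == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 9), st.integers(0, 5))
    @settings(max_examples=40, deadline=None)
    def test_strictly_increasing_in_hits(self, h, f):
        a = dprime_screening(ScreeningResponseSet(hits=h, false_alarms=f))
        b = dprime_screening(ScreeningResponseSet(hits=h + 1, false_alarms=f))
        assert b > a

    @given(st.integers(0, 10), st.integers(0, 4))
    @settings(max_examples=40, deadline=None)
    def test_strictly_decreasing_in_false_alarms(self, h, f):
        a = dprime_screening(ScreeningResponseSet(hits=h, false_alarms=f))
        b = dprime_screening(ScreeningResponseSet(hits=h, false_alarms=f + 1))
        assert b < a

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ScreeningResponseSet(hits=11, false_alarms=0)


class TestWrsFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(17)
        theta, sigma, lapse = 35.0, 4.0, 0.05
        true_srt = theta + sigma * logit(0.5 / (1 - lapse))
        srt_err, max_err = [], []
        for _ in range(100):
            levels = [20.0, 30.0, 40.0, 50.0]
            scores = [rng.binomial(25, (1 - lapse) * expit((L - theta) / sigma)) / 25
                      for L in levels]
            fit = fit_wrs_psychometric(levels, scores)
            srt_err.append(fit.srt - true_srt)
            max_err.append(fit.max_score - 95.0)
        assert np.median(np.abs(srt_err)) <= 3.0
        assert np.median(np.abs(max_err)) <= 5.0

    def test_ceiling_data_flagged(self):
        fit = fit_wrs_psychometric([30, 40, 50, 60], [1.0, 1.0, 1.0, 1.0])
        assert fit.max_score == pytest.approx(100.0, abs=1.0)
        assert fit.srt < 30.0
        assert not fit.reliable

    def test_upper_asymptote_is_free(self):
        rng = np.random.default_rng(3)
        levels = [20.0, 30.0, 40.0, 50.0]
        scores = [rng.binomial(25, 0.8 * expit((L - 22.0) / 2.0)) / 25
                  for L in levels]
        fit = fit_wrs_psychometric(levels, scores)
        assert fit.max_score == pytest.approx(80.0, abs=8.0)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_wrs_psychometric([10, 20, 30], [0.1, 0.5, 0.9])


class TestLoudnessFit:
    def noiseless_pairs(self, params, levels):
        return [(L, params.cu(L)) for L in levels]

    def test_noiseless_outcomes(self):
        params = LoudnessFunctionParams(L_cut=70.0, m_lo=0.5, m_hi=0.5,
                                        response_noise_sd=0.0)
        levels = np.linspace(25, 115, 18)
        fit = fit_loudness_function(self.noiseless_pairs(params, levels))
        assert fit.mcl == pytest.approx(70.0, abs=0.1)
        # level(50) = 120, level(0.5) = 21 -> dynamic range 99 dB
        assert fit.dyn_range == pytest.approx(99.0, abs=0.5)

    def test_noiseless_parameter_recovery(self):
        params = LoudnessFunctionParams(L_cut=75.0, m_lo=0.4, m_hi=1.2,
                                        response_noise_sd=0.0)
        levels = np.linspace(20, 100, 20)
        fit = fit_loudness_function(self.noiseless_pairs(params, levels))
        assert fit.params.L_cut == pytest.approx(75.0, abs=0.01)
        assert fit.params.m_lo == pytest.approx(0.4, abs=0.01)
        assert fit.params.m_hi == pytest.approx(1.2, abs=0.01)

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(11)
        params = LoudnessFunctionParams(L_cut=70.0, m_lo=0.45, m_hi=1.0)
        errors = []
        for _ in range(100):
            levels = np.linspace(25, 100, 25)
            pairs = [(L, float(np.clip(params.cu(L) + rng.normal(0, 3.0), 0, 50)))
                     for L in levels]
            fit = fit_loudness_function(pairs)
            errors.append(fit.slope - 0.45)
        assert np.median(np.abs(errors)) <= 0.05

    def test_nonspanning_data_flagged(self):
        pairs = [(L, 25.0 + 0.1 * (L - 70)) for L in np.linspace(65, 75, 10)]
        fit = fit_loudness_function(pairs)
        assert not fit.reliable

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_loudness_function([(50.0, 10.0)] * 5)


class TestMaskingRelease:
    def test_reference_minus_condition(self):
        assert masking_release(70.0, 55.0) == pytest.approx(15.0)

    def test_zero_for_equal_thresholds(self):
        assert masking_release(63.2, 63.2) == 0.0

    def test_negative_release_preserved(self):
        assert masking_release(60.0, 65.0) == -5.0

    def test_missing_propagates(self):
        assert masking_release(None, 60.0) is None
        assert masking_release(60.0, None) is None

    @given(st.floats(-20, 100), st.floats(-20, 100), st.floats(-30, 30))
    @settings(max_examples=40, deadline=None)
    def test_shift_invariance(self, x, y, c):
        assert masking_release(x + c, y + c) == pytest.approx(
            masking_release(x, y), abs=1e-9)


class TestBinauralPitchScore:
    def test_perfect_runs(self):
        assert score_binaural_pitch([(10, 10), (10, 10)]) == 100.0

    def test_average_over_runs(self):
        assert score_binaural_pitch([(10, 7), (10, 9)]) == pytest.approx(80.0)

    def test_diotic_hits_do_not_count(self):
        assert score_binaural_pitch([(0, 8), (10, 8)]) == pytest.approx(80.0)


class TestReduceToBear3:
    def test_column_set_matches_variable_list(self):
        rec = reduce_to_bear3({}, "L000")
        assert set(rec.values) == set(BEAR3_VARIABLES)
        assert len(ANALYSIS_VARIABLES) == 26

    def test_band_averaging_of_slopes(self):
        from bearsim.outcomes import LoudnessFit

        def fit(slope):
            params = LoudnessFunctionParams(L_cut=70, m_lo=slope, m_hi=1.0)
            return LoudnessFit(htl=0, mcl=70, slope=slope, dyn_range=90,
                               params=params)

        raw = {"acalos": {
            "left": {250: fit(0.3), 500: fit(0.3), 1000: fit(0.4)},
            "right": {250: fit(0.3), 500: fit(0.3), 1000: fit(0.4)},
        }}
        rec = reduce_to_bear3(raw, "L000")
        assert rec["Slope_LF"] == pytest.approx((0.3 + 0.3 + 0.4) / 3, abs=1e-9)

    def test_ear_averaging(self):
        raw = {"hint": {"left": {"srt_n": 4.0, "sscore_4db": 80.0},
                        "right": {"srt_n": 6.0, "sscore_4db": 90.0}}}
        rec = reduce_to_bear3(raw, "L001")
        assert rec["SRT_N"] == pytest.approx(5.0)
        assert rec["SScore_4dB"] == pytest.approx(85.0)

    def test_single_ear_used_and_flagged(self):
        raw = {"hint": {"left": {"srt_n": 4.0, "sscore_4db": 80.0},
                        "right": {"srt_n": None, "sscore_4db": None}}}
        rec = reduce_to_bear3(raw, "L002")
        assert rec["SRT_N"] == pytest.approx(4.0)
        assert rec.flags["SRT_N"] is True

    def test_missing_everywhere_propagates(self):
        rec = reduce_to_bear3({}, "L003")
        assert rec["SRT_N"] is None
        assert rec["BMR"] is None

    def test_masking_release_signs(self):
        raw = {"tin": {"left": {"N_LF": 70.0, "S_LF": 51.0, "T_LF": 63.0},
                       "right": {"N_LF": 70.0, "S_LF": 51.0, "T_LF": 63.0}}}
        rec = reduce_to_bear3(raw, "L004")
        assert rec["SMR_LF"] == pytest.approx(19.0)
        assert rec["TMR_LF"] == pytest.approx(7.0)

    def test_bmr_is_diotic_minus_dichotic(self):
        rec = reduce_to_bear3({"bmr": {"s0n0": 70.0, "spin0": 55.0}}, "L005")
        assert rec["BMR"] == pytest.approx(15.0)
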