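"""Stimulus synthesis: analytic properties of every battery stimulus."""

import numpy as np
import pytest

from bearsim.stimuli import (
    DichoticNoiseSpec, IpdSequenceSpec, MaskerSpec, ParameterError, STMSpec,
    WarbleToneSpec, band_power_per_erb, derive_condition_masker, erb_bandwidth,
    instantaneous_frequency, interaural_coherence, interaural_phase,
    ripple_contrast, synth_dichotic_noise, synth_ipd_sequence, synth_stm_noise,
    synth_ten_band, synth_warble_tone,
)


class TestWarbleTone:
    def test_excursion_is_fraction_of_carrier(self):
        # 4.3% peak excursion at 1 kHz -> 43 Hz peak deviation
        w = synth_warble_tone(WarbleToneSpec(fc=1000.0))
        f_inst = instantaneous_frequency(w)
        excursion = np.max(np.abs(f_inst - 1000.0))
        assert excursion == pytest.approx(43.0, rel=0.02)

    def test_modulation_rate(self):
        w = synth_warble_tone(WarbleToneSpec(fc=1000.0, duration=2.0))
        f_inst = instantaneous_frequency(w, trim=0.05)
        dev = f_inst - np.mean(f_inst)
        # half a modulation cycle between consecutive zero crossings
        idx = np.flatnonzero(np.abs(np.diff(np.signbit(dev))))
        span = (idx[-1] - idx[0]) / w.sample_rate
        rate = (idx.size - 1) / 2.0 / span
        assert rate == pytest.approx(4.0, rel=0.02)

    def test_zero_excursion_is_pure_tone(self):
        w = synth_warble_tone(WarbleToneSpec(fc=1000.0, fe=0.0))
        f_inst = instantaneous_frequency(w)
        assert np.allclose(f_inst, 1000.0, atol=1.0)

    def test_instantaneous_frequency_stays_within_band(self):
        spec = WarbleToneSpec(fc=2000.0, fe=0.043)
        f_inst = instantaneous_frequency(synth_warble_tone(spec))
        assert np.all(f_inst <= spec.fc * (1 + spec.fe) * 1.01)
        assert np.all(f_inst >= spec.fc * (1 - spec.fe) * 0.99)

    def test_rms_matches_requested_level(self):
        w = synth_warble_tone(WarbleToneSpec(fc=1000.0, level=70.0))
        level = w.rms_db() - 20 * np.log10(1e-5)
        # ramps remove a little energy from the nominal level
        assert level == pytest.approx(70.0, abs=0.5)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(fc=-1.0), dict(fc=1000.0, fe=1.5), dict(fc=1000.0, fr=0.0),
         dict(fc=1000.0, duration=0.05, ramp=0.05)],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            WarbleToneSpec(**kwargs)


class TestErb:
    def test_reference_value(self):
        assert erb_bandwidth(1000.0) == pytest.approx(24.7 * 5.37, abs=1e-6)

    def test_low_frequency_limit(self):
        assert erb_bandwidth(1e-6) == pytest.approx(24.7, rel=1e-3)

    def test_monotone_increasing(self):
        f = np.linspace(100, 10000, 50)
        assert np.all(np.diff(erb_bandwidth(f)) > 0)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ParameterError):
            erb_bandwidth(0.0)


class TestTenBand:
    def test_level_per_erb_at_center(self):
        spec = MaskerSpec(center=500.0, level_per_erb=70.0, duration=10.0)
        w = synth_ten_band(spec, seed=1)
        assert band_power_per_erb(w, 500.0) == pytest.approx(70.0, abs=0.5)

    def test_flat_per_erb_across_band(self):
        # any ERB-wide window fully inside the one-octave band
        spec = MaskerSpec(center=1000.0, level_per_erb=70.0, duration=10.0)
        w = synth_ten_band(spec, seed=2)
        levels = [band_power_per_erb(w, f) for f in (800, 900, 1000, 1200, 1300)]
        assert max(levels) - min(levels) < 1.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ParameterError):
            synth_ten_band(MaskerSpec(center=500.0, duration=0.0))

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            synth_ten_band(MaskerSpec(center=20000.0, sample_rate=16000.0))

    def test_reproducible_from_seed(self):
        spec = MaskerSpec(center=500.0, duration=0.5)
        a = synth_ten_band(spec, seed=7)
        b = synth_ten_band(spec, seed=7)
        assert np.array_equal(a.samples, b.samples)


class TestConditionMasker:
    def test_spectral_condition_shifts_center(self):
        base = MaskerSpec(center=2000.0)
        shifted = derive_condition_masker(2000.0, "S", base)
        assert shifted.kind == "TEN_shifted"
        assert shifted.center * shifted.shift_factor == pytest.approx(2200.0)

    def test_reference_condition_is_identity(self):
        base = MaskerSpec(center=500.0)
        assert derive_condition_masker(500.0, "N", base) == base
        # idempotent
        again = derive_condition_masker(500.0, "N", base)
        assert again == base

    def test_temporal_condition_envelope_rate(self):
        base = MaskerSpec(center=500.0, duration=4.0)
        mod = derive_condition_masker(500.0, "T", base)
        assert mod.mod_rate == 4.0
        w = synth_ten_band(mod, seed=3)
        env = np.abs(w.samples)
        # smooth the rectified signal and find the envelope periodicity
        kernel = np.ones(480) / 480
        env = np.convolve(env, kernel, mode="valid")
        spec = np.abs(np.fft.rfft(env - env.mean()))
        freqs = np.fft.rfftfreq(env.size, 1 / w.sample_rate)
        peak = freqs[np.argmax(spec)]
        assert peak == pytest.approx(4.0, abs=0.3)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ParameterError):
            derive_condition_masker(500.0, "X", MaskerSpec(center=500.0))


class TestStmNoise:
    def test_depth_from_modulation_level(self):
        assert STMSpec(modulation_level=-3.0).m == pytest.approx(0.708, abs=5e-4)

    def test_positive_modulation_level_rejected(self):
        with pytest.raises(ParameterError):
            STMSpec(modulation_level=1.0)

    def test_ripple_contrast_monotone_in_depth(self):
        contrasts = []
        for ml, unmod in ((-12.0, False), (-6.0, False), (-0.1, False)):
            spec = STMSpec(modulation_level=ml, unmodulated=unmod, duration=1.0)
            contrasts.append(ripple_contrast(synth_stm_noise(spec, seed=5), spec))
        assert contrasts[0] < contrasts[1] < contrasts[2]

    def test_unmodulated_has_no_ripple(self):
        spec = STMSpec(unmodulated=True, duration=1.0)
        mod = STMSpec(modulation_level=-3.0, duration=1.0)
        c0 = ripple_contrast(synth_stm_noise(spec, seed=6), spec)
        c1 = ripple_contrast(synth_stm_noise(mod, seed=6), mod)
        assert c0 < 0.2 * c1


class TestDichoticNoise:
    def test_interaural_phase_at_dichotic_contour(self):
        spec = DichoticNoiseSpec(
            duration=2.0, contour_freqs=(600.0,), contour_kinds=("dichotic",))
        w = synth_dichotic_noise(spec, seed=1)
        assert interaural_phase(w, 600.0, bw=30.0) == pytest.approx(np.pi, abs=0.2)

    def test_no_contours_gives_identical_channels(self):
        w = synth_dichotic_noise(DichoticNoiseSpec(duration=0.5), seed=2)
        assert np.array_equal(w.samples[0], w.samples[1])

    def test_coherent_outside_transition_bands(self):
        spec = DichoticNoiseSpec(
            duration=2.0, contour_freqs=(600.0,), contour_kinds=("dichotic",))
        w = synth_dichotic_noise(spec, seed=3)
        assert interaural_coherence(w, 1200.0, bw=100.0) > 0.95

    def test_contour_outside_band_rejected(self):
        with pytest.raises(ParameterError):
            DichoticNoiseSpec(contour_freqs=(50.0,), contour_kinds=("dichotic",))


class TestIpdSequence:
    def test_abab_tones_carry_ipd(self):
        w = synth_ipd_sequence(IpdSequenceSpec(tone_freq=500.0, pattern="ABAB"))
        sr = w.sample_rate
        tone_n = int(0.4 * sr)
        hop = int(0.5 * sr)
        phases = []
        for i in range(4):
            seg = w.samples[:, i * hop + tone_n // 4: i * hop + 3 * tone_n // 4]
            from bearsim.stimuli import Waveform
            phases.append(interaural_phase(Waveform(seg, sr), 500.0, bw=100.0))
        assert phases[0] == pytest.approx(0.0, abs=0.1)
        assert phases[1] == pytest.approx(np.pi, abs=0.1)
        assert phases[2] == pytest.approx(0.0, abs=0.1)
        assert phases[3] == pytest.approx(np.pi, abs=0.1)

    def test_aaaa_is_diotic(self):
        w = synth_ipd_sequence(IpdSequenceSpec(tone_freq=500.0, pattern="AAAA"))
        assert np.allclose(w.samples[0], w.samples[1])

    def test_zero_ipd_abab_equals_aaaa(self):
        a = synth_ipd_sequence(IpdSequenceSpec(pattern="ABAB", ipd=0.0))
        b = synth_ipd_sequence(IpdSequenceSpec(pattern="AAAA"))
        assert np.allclose(a.samples, b.samples)
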