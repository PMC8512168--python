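"""Simulated listeners and cohort generation.

A :class:`ListenerProfile` holds the generative ground truth of one
simulated subject: an audiogram, per-band loudness functions, speech,
spectro-temporal and binaural parameters, and response-noise parameters
(false-alarm and lapse rates).  Response methods turn a profile into the
yes/no, categorical and 2-AFC answers the adaptive procedures need.

:func:`make_cohort` generates populations with the statistical structure
the battery is designed to expose: audiograms spanning the standard
audiograms N1-N4, loudness recruitment growing with high-frequency loss,
speech-in-noise and spectro-temporal deficits correlated with
high-frequency loss, and binaural abilities statistically independent of
the audiogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
from scipy.special import expit

__all__ = [
    "PsychometricParams",
    "LoudnessFunctionParams",
    "ListenerProfile",
    "CohortConfig",
    "psychometric_prob",
    "respond_yesno",
    "respond_loudness",
    "respond_2afc_ipd",
    "make_cohort",
    "STANDARD_AUDIOGRAMS",
    "AUDIOGRAM_FREQS",
]


# ---------------------------------------------------------------------------
# Parameter records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsychometricParams:
    """Logistic psychometric function with guess and lapse rates."""

    theta: float
    sigma: float = 2.0
    gamma: float = 0.0
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0 <= self.gamma and 0 <= self.lapse and self.gamma + self.lapse < 1):
            raise ValueError("gamma and lapse must be >= 0 with gamma+lapse < 1")


@dataclass(frozen=True)
class LoudnessFunctionParams:
    """Broken-stick categorical loudness function.

    CU(L) = 25 + m_lo*(L - L_cut) below the cut level and
    25 + m_hi*(L - L_cut) above, clipped to [0, 50]; categorical
    responses add Gaussian noise of ``response_noise_sd`` CU before
    snapping to the 11 response categories.
    """

    L_cut: float
    m_lo: float
    m_hi: float
    response_noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.m_lo <= 0 or self.m_hi <= 0:
            raise ValueError("loudness slopes must be positive")

    def cu(self, level: float) -> float:
        """Noiseless CU at ``level`` dB."""
        level = np.asarray(level, dtype=float)
        lo = 25.0 + self.m_lo * (level - self.L_cut)
        hi = 25.0 + self.m_hi * (level - self.L_cut)
        out = np.where(level <= self.L_cut, lo, hi)
        return float(np.clip(out, 0.0, 50.0)) if out.ndim == 0 else np.clip(out, 0, 50)

    def level_at(self, cu: float) -> float:
        """Inverse of the (unclipped) broken-stick function."""
        if cu <= 25.0:
            return self.L_cut + (cu - 25.0) / self.m_lo
        return self.L_cut + (cu - 25.0) / self.m_hi


AUDIOGRAM_FREQS: tuple[float, ...] = (250, 500, 1000, 2000, 3000, 4000, 6000, 8000)

# IEC 60118-15 standard audiograms (Bisgaard et al. 2010), dB HL.
# Published at 250-6000 Hz; 8 kHz continues the 4->6 kHz slope.
STANDARD_AUDIOGRAMS: dict[str, tuple[float, ...]] = {
    "N1": (10, 10, 10, 15, 20, 30, 40, 50),
    "N2": (20, 20, 25, 35, 40, 45, 50, 55),
    "N3": (35, 35, 40, 50, 55, 60, 65, 70),
    "N4": (55, 55, 55, 65, 70, 75, 80, 85),
}


@dataclass(frozen=True)
class ListenerProfile:
    """Generative ground truth of one simulated listener.

    Threshold-type fields are in dB (HL unless noted); ``flft_true`` and
    ``ipd_fmax_true`` in Hz; ``stm_threshold`` in dB modulation level.
    ``tin_true`` maps ``(condition, band)`` -> masked threshold, with
    condition in {"N", "S", "T"} and band in {"LF", "HF"}.
    """

    listener_id: str
    audiogram: Mapping[float, float]
    flft_true: float
    loudness: Mapping[float, LoudnessFunctionParams]
    speech_quiet: PsychometricParams
    speech_noise: PsychometricParams
    stm_threshold: Mapping[str, float]
    stm_sigma: float
    tin_true: Mapping[str, float]
    s0n0_true: float
    spin0_true: float
    ipd_fmax_true: float
    ipd_spread_oct: float
    bp_detect_prob: float
    false_alarm_rate: float = 0.05
    lapse_rate: float = 0.02
    detection_sigma: float = 2.0
    group: str = "HI"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.bp_detect_prob, self.false_alarm_rate, self.lapse_rate):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")

    # -- ground-truth helpers -------------------------------------------

    def pta(self, freqs=(500, 1000, 2000)) -> float:
        """Pure-tone average over ``freqs`` (dB HL)."""
        return float(np.mean([self.audiogram[f] for f in freqs]))

    def band_mean(self, band: str) -> float:
        freqs = (250, 500, 1000) if band == "LF" else (2000, 4000, 6000)
        return float(np.mean([self.audiogram[f] for f in freqs]))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["audiogram"] = {str(k): v for k, v in self.audiogram.items()}
        d["loudness"] = {str(k): asdict(v) for k, v in self.loudness.items()}
        d["stm_threshold"] = dict(self.stm_threshold)
        d["tin_true"] = dict(self.tin_true)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ListenerProfile":
        d = dict(d)
        d["audiogram"] = {float(k): v for k, v in d["audiogram"].items()}
        d["loudness"] = {
            float(k): LoudnessFunctionParams(**v) for k, v in d["loudness"].items()
        }
        d["speech_quiet"] = PsychometricParams(**d["speech_quiet"])
        d["speech_noise"] = PsychometricParams(**d["speech_noise"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Response models
# ---------------------------------------------------------------------------


def psychometric_prob(x: float, params: PsychometricParams) -> float:
    """gamma + (1 - gamma - lapse) * logistic((x - theta)/sigma)."""
    f = expit((np.asarray(x, dtype=float) - params.theta) / params.sigma)
    return params.gamma + (1.0 - params.gamma - params.lapse) * f


def _threshold_for(profile: ListenerProfile, test_id: str) -> tuple[float, float]:
    """(threshold, easier_sign) for a yes/no test; sign +1 when larger
    tracked values are easier."""
    if test_id == "eAUD-HF":
        return profile.flft_true, -1.0
    if test_id.startswith("eAUD-"):
        cond, band = test_id.split("-")[1].split("_")
        return profile.tin_true[f"{cond}_{band}"], 1.0
    if test_id.startswith("fSTM"):
        band = test_id.split("_")[1]
        return profile.stm_threshold[band], 1.0
    if test_id == "S0N0":
        return profile.s0n0_true, 1.0
    if test_id == "SpiN0":
        return profile.spin0_true, 1.0
    raise KeyError(f"unknown yes/no test id {test_id!r}")


def respond_yesno(
    profile: ListenerProfile,
    test_id: str,
    stimulus_present: bool,
    tracked_value: float,
    rng: np.random.Generator,
) -> bool:
    """Yes/no response for any SIAM-tracked test.

    Catch trials draw a yes with the profile's false-alarm rate; signal
    trials follow the listener's psychometric function around the
    ground-truth threshold for ``test_id``.  Frequency-domain tests
    (high-frequency audiometry, tracked in Hz) evaluate the function in
    log2 units with an octave-scaled spread.
    """
    if not stimulus_present:
        return bool(rng.random() < profile.false_alarm_rate)
    theta, easier = _threshold_for(profile, test_id)
    if test_id == "eAUD-HF":
        # frequency track: evaluate in log2 units, lower frequency = easier
        x, th = np.log2(tracked_value), np.log2(theta)
        sigma = 0.08  # octaves
    else:
        x, th = tracked_value, theta
        sigma = (profile.stm_sigma if test_id.startswith("fSTM")
                 else profile.detection_sigma)
    params = PsychometricParams(
        theta=0.0, sigma=sigma,
        gamma=profile.false_alarm_rate, lapse=profile.lapse_rate,
    )
    p = psychometric_prob(easier * (x - th), params)
    return bool(rng.random() < p)


def respond_loudness(
    profile: ListenerProfile, band: float, level: float, rng: np.random.Generator
) -> float:
    """Categorical loudness response (one of the 11 CU categories)."""
    from .adaptive import CU_CATEGORIES

    params = profile.loudness[band]
    cu = params.cu(level)
    if cu <= 0:  # below threshold: "not heard", no noise
        return 0.0
    cu = cu + rng.normal(0.0, params.response_noise_sd)
    cats = np.asarray(CU_CATEGORIES)
    return float(cats[np.argmin(np.abs(cats - cu))])


def respond_2afc_ipd(
    profile: ListenerProfile, freq: float, rng: np.random.Generator
) -> bool:
    """Positive (detection) response in the interaural-phase-limit test.

    The listener hears two four-tone sequences and reports whether one of
    them contained the phase-alternating tones.  The probability of a
    positive response is ``fa + (1 - fa - lapse) * S(freq)`` where the
    binaural sensitivity ``S`` falls from 1 to 0 around
    ``ipd_fmax_true`` with spread ``ipd_spread_oct`` octaves (S = 0.5 at
    the limit).  Driving the 1-up/1-down track with the detection report
    anchors it at the limit frequency; scoring raw two-interval
    correctness instead would leave the track adrift above the limit,
    where choices are pure coin flips.
    """
    z = (np.log2(freq) - np.log2(profile.ipd_fmax_true)) / profile.ipd_spread_oct
    s = float(expit(-z))  # falls from 1 to 0 around the limit; S = 0.5 at it
    p = profile.false_alarm_rate + (
        1.0 - profile.false_alarm_rate - profile.lapse_rate) * s
    return bool(rng.random() < p)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings of a simulated cohort.

    Audiograms are indexed in the standard-audiogram family by two latent
    severity scalars — one for the low-frequency side (<= 1 kHz), one for
    the high-frequency side (>= 2 kHz) — each interpolating N1 (0) to N4
    (3).  The two severities are drawn with correlation
    ``severity_corr``; keeping it well below 1 is what gives the outcome
    table its separate low- and high-frequency correlation clusters.
    ``onh_fraction`` of listeners are forced to near-normal hearing.
    Linkage coefficients tie supra-threshold ground truths to the
    low/high-frequency hearing losses; binaural parameters are drawn
    independently of the audiogram.
    """

    n_listeners: int = 50
    onh_fraction: float = 0.1
    severity_range: tuple[float, float] = (0.0, 3.0)
    severity_corr: float = 0.3
    audiogram_jitter_sd: float = 5.0
    # loudness recruitment: the lower-branch slope (the battery's "Slope")
    # steepens with the local hearing loss, 0.33 CU/dB at no loss;
    # the upper branch starts at 1.0 CU/dB and steepens mildly
    recruitment_coef: float = 0.78
    mhi_coef: float = 0.5
    # speech linkages (dB outcome per dB of loss); the quiet SRT sits
    # ~10 dB above the PTA so the four presentation levels (PTA+10..40)
    # bracket the 50% point as in the real test design
    srtq_pta_coef: float = 1.0
    srtq_offset: float = 10.0
    srtn_hf_coef: float = 0.10
    srtn_noise_sd: float = 0.8
    # spectro-temporal linkages (dB ML per dB HF loss)
    stm_hf_coef: float = 0.12
    stm_noise_sd: float = 1.0
    # masking-release deficits (dB of release lost per dB HF loss)
    smr_hf_coef: float = 0.15
    tmr_hf_coef: float = 0.10
    # independent binaural distributions
    ipd_fmax_log2_mean: float = np.log2(750.0)
    ipd_fmax_log2_sd: float = 0.35
    bp_fail_fraction: float = 0.15
    bmr_mean: float = 15.0
    bmr_sd: float = 4.5
    false_alarm_rate: float = 0.05
    lapse_rate: float = 0.02
    detection_sigma: float = 2.0
    stm_sigma: float = 1.5
    speech_sigma_quiet: float = 4.0
    speech_sigma_noise: float = 1.5
    ipd_spread_oct: float = 0.1
    loudness_noise_sd: float = 3.0
    noise_free: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_listeners < 1:
            raise ValueError("cohort must contain at least one listener")
        if self.noise_free:
            # deterministic listeners: no response noise, step-like
            # psychometric functions, probabilities snapped to 0/1
            object.__setattr__(self, "false_alarm_rate", 0.0)
            object.__setattr__(self, "lapse_rate", 0.0)
            object.__setattr__(self, "detection_sigma", 0.01)
            object.__setattr__(self, "stm_sigma", 0.01)
            object.__setattr__(self, "speech_sigma_quiet", 0.05)
            object.__setattr__(self, "speech_sigma_noise", 0.05)
            object.__setattr__(self, "ipd_spread_oct", 0.01)
            object.__setattr__(self, "loudness_noise_sd", 0.0)


def _interp_standard_audiogram(severity: float) -> np.ndarray:
    """Piecewise-linear interpolation between N1..N4 at ``severity`` in [0, 3]."""
    grids = np.asarray([STANDARD_AUDIOGRAMS[k] for k in ("N1", "N2", "N3", "N4")])
    s = float(np.clip(severity, 0.0, 3.0))
    i = min(int(np.floor(s)), 2)
    w = s - i
    return (1 - w) * grids[i] + w * grids[i + 1]


def make_cohort(config: CohortConfig) -> list[ListenerProfile]:
    """Generate a reproducible cohort of simulated listeners.

    Audiograms are sampled from the N1-N4 standard-audiogram family with
    per-frequency Gaussian jitter.  Supra-threshold ground truths are
    affine in the low/high-frequency hearing losses plus independent
    noise; binaural ground truths are drawn independently of the
    audiogram.
    """
    rng = np.random.default_rng(config.seed)
    profiles: list[ListenerProfile] = []
    n_onh = int(round(config.onh_fraction * config.n_listeners))
    nh_template = np.array([0.0, 0.0, 0.0, 5.0, 5.0, 5.0, 10.0, 15.0])
    for i in range(config.n_listeners):
        onh = i < n_onh
        if onh:
            base = nh_template
            jitter = rng.normal(0.0, 2.0, base.size)
        else:
            # two latent severities (LF, HF) with partial correlation
            z = rng.standard_normal(2)
            r = config.severity_corr
            z[1] = r * z[0] + np.sqrt(1 - r**2) * z[1]
            lo, hi = config.severity_range
            from scipy.stats import norm as _norm
            sev_lf, sev_hf = lo + (hi - lo) * _norm.cdf(z)
            curve_lf = _interp_standard_audiogram(sev_lf)
            curve_hf = _interp_standard_audiogram(sev_hf)
            freqs = np.asarray(AUDIOGRAM_FREQS, dtype=float)
            w_hf = np.clip(np.log2(freqs / 1000.0), 0.0, 1.0)  # 0 at <=1k, 1 at >=2k
            base = (1 - w_hf) * curve_lf + w_hf * curve_hf
            jitter = rng.normal(0.0, config.audiogram_jitter_sd, base.size)
        thresholds = np.clip(base + jitter, -10.0, 110.0)
        audiogram = dict(zip(AUDIOGRAM_FREQS, thresholds.astype(float)))
        lf = float(np.mean([audiogram[f] for f in (250, 500, 1000)]))
        hf = float(np.mean([audiogram[f] for f in (2000, 4000, 6000)]))
        pta = float(np.mean([audiogram[f] for f in (500, 1000, 2000)]))

        # maximum audible frequency at 80 dB SPL falls with HF loss
        flft = 16000.0 * 2.0 ** (-(audiogram[8000] / 60.0)) + rng.normal(0, 200)
        flft = float(np.clip(flft, 2000.0, 18000.0))

        loudness: dict[float, LoudnessFunctionParams] = {}
        for f in (250, 500, 1000, 2000, 4000, 6000):
            loss = audiogram[f]
            m_lo = 0.33 + config.recruitment_coef * max(loss, 0.0) / 100.0 \
                + rng.normal(0, 0.02)
            m_hi = 1.0 + config.mhi_coef * max(loss, 0.0) / 100.0 \
                + rng.normal(0, 0.05)
            m_lo, m_hi = max(m_lo, 0.1), max(m_hi, 0.2)
            # anchor: ACALOS hearing threshold (CU 2.5) sits at the
            # audiometric threshold
            L_cut = loss + 22.5 / m_lo + rng.normal(0, 2.0)
            loudness[float(f)] = LoudnessFunctionParams(
                L_cut=float(L_cut), m_lo=float(m_lo), m_hi=float(m_hi),
                response_noise_sd=config.loudness_noise_sd,
            )

        lapse_q = 0.0 if config.noise_free else float(
            np.clip(0.01 + 0.002 * max(hf - 30, 0.0) + rng.normal(0, 0.01),
                    0.0, 0.3))
        speech_quiet = PsychometricParams(
            theta=float(config.srtq_offset + config.srtq_pta_coef * pta
                        + rng.normal(0, 3.0)),
            sigma=config.speech_sigma_quiet,
            gamma=0.0,
            lapse=lapse_q,
        )
        speech_noise = PsychometricParams(
            theta=float(-1.0 + config.srtn_hf_coef * max(hf - 10.0, 0.0)
                        + rng.normal(0, config.srtn_noise_sd)),
            sigma=config.speech_sigma_noise,
            gamma=0.0,
            lapse=0.0 if config.noise_free else 0.01,
        )

        stm = {
            "LF": float(np.clip(-8.0 + config.stm_hf_coef * max(hf - 10, 0)
                                + rng.normal(0, config.stm_noise_sd), -20.0, -0.5)),
            "HF": float(np.clip(-6.0 + config.stm_hf_coef * 1.3 * max(hf - 10, 0)
                                + rng.normal(0, config.stm_noise_sd), -20.0, -0.5)),
        }

        # tone-in-noise: reference tracks the 70 dB/ERB noise level with a
        # small efficiency penalty for HF loss; S and T release shrink
        # with HF loss
        tin: dict[str, float] = {}
        for band, loss in (("LF", lf), ("HF", hf)):
            ref = 70.0 + 0.03 * max(loss - 20, 0.0) + rng.normal(0, 2.5)
            smr_nh = 19.0 if band == "LF" else 27.0
            tmr_nh = 7.0 if band == "LF" else 11.0
            hf_excess = max(hf - 20.0, 0.0)
            smr = max(smr_nh - config.smr_hf_coef * (hf_excess if band == "HF" else 0.0)
                      + rng.normal(0, 3.0), 0.0)
            tmr = max(tmr_nh - config.tmr_hf_coef * (hf_excess if band == "HF" else 0.0)
                      + rng.normal(0, 3.0), 0.0)
            tin[f"N_{band}"] = float(ref)
            tin[f"S_{band}"] = float(ref - smr)
            tin[f"T_{band}"] = float(ref - tmr)

        # binaural ground truths: independent of the audiogram
        ipd_fmax = float(2.0 ** rng.normal(config.ipd_fmax_log2_mean,
                                           config.ipd_fmax_log2_sd))
        bp_fail = rng.random() < config.bp_fail_fraction
        bp_detect = float(rng.uniform(0.2, 0.8)) if bp_fail else float(
            rng.uniform(0.95, 1.0))
        if config.noise_free:
            bp_detect = float(round(bp_detect))
        bmr = float(max(rng.normal(config.bmr_mean, config.bmr_sd), 2.0))
        s0n0 = float(70.0 + rng.normal(0, 1.0))

        profiles.append(
            ListenerProfile(
                listener_id=f"L{i:03d}",
                audiogram=audiogram,
                flft_true=flft,
                loudness=loudness,
                speech_quiet=speech_quiet,
                speech_noise=speech_noise,
                stm_threshold=stm,
                stm_sigma=config.stm_sigma,
                tin_true=tin,
                s0n0_true=s0n0,
                spin0_true=float(s0n0 - bmr),
                ipd_fmax_true=ipd_fmax,
                ipd_spread_oct=config.ipd_spread_oct,
                bp_detect_prob=bp_detect,
                false_alarm_rate=config.false_alarm_rate,
                lapse_rate=config.lapse_rate,
                detection_sigma=config.detection_sigma,
                group="ONH" if onh else "HI",
                seed=int(config.seed) * 100_000 + i,
            )
        )
    return profiles


def save_cohort(profiles: list[ListenerProfile], path: str) -> None:
    """Write profiles as a JSON list (lossless round trip)."""
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in profiles], fh, indent=1)


def load_cohort(path: str) -> list[ListenerProfile]:
    with open(path) as fh:
        return [ListenerProfile.from_dict(d) for d in json.load(fh)]
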