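"""Battery orchestration: run every test for a listener or a cohort.

:func:`run_full_battery` wires the simulated listener's response models
into each test's adaptive engine, applies the battery-wide repetition
and validity policy to the repeated runs, and reduces the raw outcomes
to the 26-variable analysis record.  Everything is reproducible from the
pair (profile, master seed): per-test seeds are derived with a seed
sequence, so enabling or disabling one test does not change another's
trials.

:func:`run_cohort_study` maps the battery over a cohort and optionally
re-runs it with fresh seeds to produce retest tables for the
reliability analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import adaptive, observers, outcomes
from .adaptive import (
    AcalosConfig, HintConfig, SIAM_PRESETS, SiamConfig, TwoAfcConfig,
    repetition_policy, run_2afc_frequency_track, run_acalos_track, run_hint,
    run_siam_track,
)
from .observers import (
    ListenerProfile, psychometric_prob, respond_2afc_ipd, respond_loudness,
    respond_yesno, PsychometricParams,
)
from .outcomes import (
    OutcomeRecord, ScreeningResponseSet, dprime_screening,
    fit_loudness_function, fit_wrs_psychometric, reduce_to_bear3,
    score_binaural_pitch,
)

__all__ = [
    "BatteryConfig",
    "RunManifest",
    "run_full_battery",
    "run_cohort_study",
    "select_foils",
    "levenshtein",
]

ALL_TESTS: tuple[str, ...] = (
    "audiogram", "eAUD-HF", "ACALOS", "WRS", "HINT", "sSTM", "fSTM",
    "eAUD", "IPD", "BP", "BMR",
)

EARS = ("left", "right")


@dataclass(frozen=True)
class BatteryConfig:
    """Which tests to run and how.

    ``repetitions`` is the number of initial runs for the adaptive
    threshold tests (the paper's policy: at least two, extra ones when
    the runs disagree).  ``calibration`` maps dB HL to dB SPL offsets per
    frequency; the default identity table keeps every level in dB HL.
    """

    enabled: tuple[str, ...] = ALL_TESTS
    repetitions: int = 2
    max_extra_repetitions: int = 2
    master_seed: int = 0
    acalos_bands: tuple[float, ...] = (250.0, 500.0, 1000.0, 2000.0, 4000.0, 6000.0)
    wrs_levels_re_pta: tuple[float, ...] = (40.0, 30.0, 20.0, 10.0)
    wrs_words_per_level: int = 25
    bmr_tone_freq: float = 500.0
    siam_overrides: Mapping[str, SiamConfig] = field(default_factory=dict)
    calibration: Mapping[float, float] = field(default_factory=dict)

    def siam(self, name: str) -> SiamConfig:
        return self.siam_overrides.get(name, SIAM_PRESETS[name])


@dataclass
class RunManifest:
    """Per-test bookkeeping of one battery run."""

    listener_id: str
    master_seed: int
    status: dict = field(default_factory=dict)       # test -> done/repeated/missing
    extra_repetitions: dict = field(default_factory=dict)
    trial_counts: dict = field(default_factory=dict)

    def note(self, test: str, status: str, extras: int = 0, trials: int = 0) -> None:
        self.status[test] = status
        if extras:
            self.extra_repetitions[test] = (
                self.extra_repetitions.get(test, 0) + extras
            )
        self.trial_counts[test] = self.trial_counts.get(test, 0) + trials


def _repeated_siam(
    profile: ListenerProfile,
    test_id: str,
    config: SiamConfig,
    rng_children: list,
    n_runs: int,
    max_extra: int,
    manifest: RunManifest,
    manifest_key: str,
) -> float | None:
    """Run a SIAM test with the battery's repetition policy."""
    estimates: list[float | None] = []
    bounds: list[bool] = []
    trials = 0
    child_iter = iter(rng_children)

    def one_run():
        nonlocal trials
        track = run_siam_track(
            lambda present, value, rng: respond_yesno(
                profile, test_id, present, value, rng),
            config,
            np.random.default_rng(next(child_iter)),
        )
        trials += len(track.trials)
        estimates.append(track.threshold_estimate)
        bounds.append(track.invalid_reason == "bounds_hit")

    for _ in range(n_runs):
        one_run()
    extras = 0
    decision, value = repetition_policy(estimates, bounds)
    while decision == "repeat" and extras < max_extra:
        one_run()
        extras += 1
        decision, value = repetition_policy(estimates, bounds)
    if decision == "repeat":
        # could not resolve the outlier within the allowed repetitions:
        # fall back to the median of the valid runs
        valid = [e for e, b in zip(estimates, bounds) if e is not None and not b]
        value = float(np.median(valid))
        decision = "accept"
    status = {"accept": "repeated" if extras else "done",
              "missing": "missing"}[decision]
    manifest.note(manifest_key, status, extras, trials)
    return value


def run_full_battery(
    profile: ListenerProfile, config: BatteryConfig = BatteryConfig()
) -> tuple[OutcomeRecord, RunManifest, dict]:
    """Run every enabled test for one simulated listener.

    Returns the reduced outcome record, the run manifest, and the raw
    per-test results (trial logs and fits) keyed by test name.
    """
    ss = np.random.SeedSequence([config.master_seed, profile.seed])
    seeds = iter(ss.generate_state(4096))
    manifest = RunManifest(profile.listener_id, config.master_seed)
    raw: dict = {}
    logs: dict = {}

    enabled = set(config.enabled)

    if "audiogram" in enabled:
        rng = np.random.default_rng(next(seeds))
        aud = {}
        for ear in EARS:
            # clinical audiometry: 5-dB steps, small measurement noise
            aud[ear] = {
                f: float(5 * round((t + rng.normal(0, 1.5)) / 5))
                for f, t in profile.audiogram.items()
            }
        raw["audiogram"] = aud
        manifest.note("audiogram", "done")

    if "eAUD-HF" in enabled:
        raw["flft"] = {}
        for ear in EARS:
            children = [next(seeds) for _ in range(config.repetitions
                                                   + config.max_extra_repetitions)]
            raw["flft"][ear] = _repeated_siam(
                profile, "eAUD-HF", config.siam("eAUD-HF"), children,
                config.repetitions, config.max_extra_repetitions,
                manifest, "eAUD-HF",
            )

    if "ACALOS" in enabled:
        raw["acalos"] = {}
        for ear in EARS:
            fits = {}
            for band in config.acalos_bands:
                pairs = run_acalos_track(
                    lambda level, rng, b=band: respond_loudness(
                        profile, b, level, rng),
                    AcalosConfig(band_center=band),
                    np.random.default_rng(next(seeds)),
                )
                fits[band] = fit_loudness_function(pairs)
                manifest.note("ACALOS", "done", trials=len(pairs))
            raw["acalos"][ear] = fits

    if "WRS" in enabled:
        raw["wrs"] = {}
        pta = profile.pta()
        levels = [pta + d for d in config.wrs_levels_re_pta]
        for ear in EARS:
            rng = np.random.default_rng(next(seeds))
            scores = []
            for level in levels:
                p = psychometric_prob(level, profile.speech_quiet)
                scores.append(
                    rng.binomial(config.wrs_words_per_level, p)
                    / config.wrs_words_per_level
                )
            raw["wrs"][ear] = fit_wrs_psychometric(
                levels, scores, config.wrs_words_per_level)
            manifest.note("WRS", "done",
                          trials=len(levels) * config.wrs_words_per_level)

    if "HINT" in enabled:
        raw["hint"] = {}
        for ear in EARS:
            def sentence(snr, rng):
                return rng.random() < psychometric_prob(snr, profile.speech_noise)

            track = run_hint(sentence, "adaptive_srt", HintConfig(),
                             np.random.default_rng(next(seeds)))
            # the staircase tracks decreasing SNR on correct: easier = higher
            score = run_hint(sentence, "fixed_snr", HintConfig(),
                             np.random.default_rng(next(seeds)))
            raw["hint"][ear] = {"srt_n": track.threshold_estimate,
                                "sscore_4db": score}
            manifest.note("HINT", "done", trials=2 * HintConfig().n_sentences)

    stm_raw: dict = {}
    if "sSTM" in enabled:
        for key, band in (("sSTM_8", "LF"), ("sSTM_4k", "HF")):
            rng = np.random.default_rng(next(seeds))
            dprimes = []
            for _ in range(2):
                p_hit = psychometric_prob(
                    -3.0,
                    PsychometricParams(
                        theta=profile.stm_threshold[band],
                        sigma=profile.stm_sigma,
                        gamma=profile.false_alarm_rate,
                        lapse=profile.lapse_rate,
                    ),
                )
                hits = int(rng.binomial(10, p_hit))
                fas = int(rng.binomial(5, profile.false_alarm_rate))
                dprimes.append(dprime_screening(
                    ScreeningResponseSet(hits=hits, false_alarms=fas)))
            stm_raw[key] = float(np.mean(dprimes))
            manifest.note("sSTM", "done", trials=30)

    if "fSTM" in enabled:
        for key, band in (("fSTM_8", "LF"), ("fSTM_4k", "HF")):
            stm_raw[key] = {}
            for ear in EARS:
                children = [next(seeds) for _ in range(
                    config.repetitions + config.max_extra_repetitions)]
                stm_raw[key][ear] = _repeated_siam(
                    profile, f"fSTM_{band}", config.siam("fSTM"), children,
                    config.repetitions, config.max_extra_repetitions,
                    manifest, "fSTM",
                )
    if stm_raw:
        raw["stm"] = stm_raw

    if "eAUD" in enabled:
        raw["tin"] = {}
        for ear in EARS:
            table = {}
            for cond in ("N", "S", "T"):
                for band in ("LF", "HF"):
                    children = [next(seeds) for _ in range(
                        config.repetitions + config.max_extra_repetitions)]
                    table[f"{cond}_{band}"] = _repeated_siam(
                        profile, f"eAUD-{cond}_{band}",
                        config.siam(f"eAUD-{cond}"), children,
                        config.repetitions, config.max_extra_repetitions,
                        manifest, f"eAUD-{cond}",
                    )
            raw["tin"][ear] = table

    if "IPD" in enabled:
        runs = []
        trials = 0
        for _ in range(2):
            track = run_2afc_frequency_track(
                lambda freq, rng: respond_2afc_ipd(profile, freq, rng),
                TwoAfcConfig(),
                np.random.default_rng(next(seeds)),
            )
            trials += len(track.trials)
            if track.valid:
                runs.append(track.threshold_estimate)
        if runs:
            # average the run estimates in log2-frequency
            raw["ipd_fmax"] = float(2.0 ** np.mean(np.log2(runs)))
            manifest.note("IPD", "done", trials=trials)
        else:
            manifest.note("IPD", "missing", trials=trials)

    if "BP" in enabled:
        rng = np.random.default_rng(next(seeds))
        runs = []
        for _ in range(2):
            diotic = int(rng.binomial(10, 0.98))
            dichotic = int(rng.binomial(10, profile.bp_detect_prob))
            runs.append((diotic, dichotic))
        raw["bp20"] = score_binaural_pitch(runs)
        manifest.note("BP", "done", trials=40)

    if "BMR" in enabled:
        bmr = {}
        for key, test_id in (("s0n0", "S0N0"), ("spin0", "SpiN0")):
            children = [next(seeds) for _ in range(
                config.repetitions + config.max_extra_repetitions)]
            bmr[key] = _repeated_siam(
                profile, test_id, config.siam(test_id), children,
                config.repetitions, config.max_extra_repetitions,
                manifest, test_id,
            )
        raw["bmr"] = bmr

    record = reduce_to_bear3(raw, profile.listener_id, profile.group,
                             seed=config.master_seed)
    return record, manifest, raw


def run_cohort_study(
    cohort: Sequence[ListenerProfile],
    config: BatteryConfig = BatteryConfig(),
    retest: bool = False,
):
    """Run the battery over a cohort; optionally a retest session.

    The retest session re-runs every test with fresh derived seeds
    (same listeners, same config), emulating a second visit.  Returns
    ``(table, manifests)`` or ``(table, retest_table, manifests)`` as
    pandas DataFrames.
    """
    from .outcomes import records_to_frame

    def session(offset: int):
        records, manifests = [], []
        for profile in cohort:
            rec, man, _ = run_full_battery(
                profile, replace(config, master_seed=config.master_seed + offset))
            records.append(rec)
            manifests.append(man)
        return records_to_frame(records), manifests

    table, manifests = session(0)
    if not retest:
        return table, manifests
    retable, remanifests = session(7_654_321)
    return table, retable, manifests + remanifests


# ---------------------------------------------------------------------------
# Word-list utilities
# ---------------------------------------------------------------------------


def levenshtein(a: str, b: str) -> int:
    """Plain character-level edit distance."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def select_foils(target_word: str, corpus: Sequence[str], k: int = 3) -> list[str]:
    """Pick the ``k`` corpus words closest to the target in edit distance.

    The target itself (any occurrence) is excluded; ties are broken
    lexicographically.  Raises when the corpus has fewer than ``k``
    candidate words.
    """
    candidates = sorted({w for w in corpus if w != target_word})
    if len(candidates) < k:
        raise ValueError("corpus too small for the requested number of foils")
    ranked = sorted(candidates, key=lambda w: (levenshtein(target_word, w), w))
    return ranked[:k]
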