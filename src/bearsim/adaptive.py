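"""Adaptive psychophysical procedures.

The battery uses four families of adaptive procedures:

* **SIAM yes/no tracks** (single-interval adjustment matrix, Kaernbach
  1990) with interleaved catch trials, used for high-frequency
  audiometry, tone-in-noise detection, and the fast spectro-temporal
  modulation test.  The step applied after each trial is the current
  step size times a payoff multiplier that depends on the targeted hit
  probability ``t`` (see :func:`siam_deltas`).
* **2-AFC 1-up/1-down frequency tracks** in log2-frequency for the
  interaural-phase-limit test.
* **Adaptive categorical loudness scaling** (two phases: dynamic-range
  bracketing, then level placement across the range).
* **Sentence staircases** for speech-in-noise (adaptive SRT or fixed-SNR
  scoring).

Observers are duck-typed callables supplied by :mod:`bearsim.observers`;
every run is reproducible from ``(config, observer, seed)``.

Tracked values are maintained in continuous units throughout; rounding
happens only at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "SiamConfig",
    "TrialRecord",
    "TrackResult",
    "TwoAfcConfig",
    "AcalosConfig",
    "HintConfig",
    "siam_deltas",
    "run_siam_track",
    "estimate_threshold",
    "run_2afc_frequency_track",
    "run_acalos_track",
    "run_hint",
    "repetition_policy",
    "SIAM_PRESETS",
    "CU_CATEGORIES",
]


# ---------------------------------------------------------------------------
# Configs and records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiamConfig:
    """Configuration of one SIAM yes/no track.

    ``easier_sign`` maps the abstract "easier" direction onto the tracked
    unit: +1 when larger values are easier (tone level in noise,
    modulation level in dB ML), -1 when smaller values are easier
    (warble-tone frequency near the audibility limit).
    """

    target_prob: float = 0.5
    initial_value: float = 0.0
    easier_sign: float = 1.0
    step_schedule: Sequence[float] = (8.0, 4.0, 2.0)
    catch_rate: float = 0.2
    max_trials: int = 200
    bounds: tuple[float, float] = (-20.0, 120.0)
    discard_reversals: int = 2
    average_reversals: int = 4
    log2_domain: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.target_prob < 1):
            raise ValueError("target probability must lie in (0, 1)")
        if any(s <= 0 for s in self.step_schedule):
            raise ValueError("step sizes must be positive")

    @property
    def n_reversals(self) -> int:
        return self.discard_reversals + self.average_reversals


@dataclass(frozen=True)
class TrialRecord:
    index: int
    stimulus_present: bool
    tracked_value: float
    response: bool
    outcome: Literal["hit", "miss", "false_alarm", "correct_rejection"]
    step_applied: float
    reversal_flag: bool

    def __post_init__(self) -> None:
        table = {
            (True, True): "hit",
            (True, False): "miss",
            (False, True): "false_alarm",
            (False, False): "correct_rejection",
        }
        if table[(self.stimulus_present, self.response)] != self.outcome:
            raise ValueError("outcome inconsistent with stimulus/response")

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "stimulus_present": self.stimulus_present,
            "tracked_value": self.tracked_value,
            "response": self.response,
            "outcome": self.outcome,
            "step_applied": self.step_applied,
            "reversal_flag": self.reversal_flag,
        }


@dataclass(frozen=True)
class TrackResult:
    """Trial log and estimate of one adaptive run."""

    trials: tuple[TrialRecord, ...]
    reversal_values: tuple[float, ...]
    threshold_estimate: float | None
    valid: bool
    invalid_reason: Literal["bounds_hit", "inconsistent", "none"] = "none"

    def __post_init__(self) -> None:
        if self.valid and self.threshold_estimate is None:
            raise ValueError("valid track must carry a threshold estimate")

    def to_jsonl(self) -> str:
        import json

        return "\n".join(json.dumps(t.to_dict()) for t in self.trials)


@dataclass(frozen=True)
class TwoAfcConfig:
    """1-up/1-down 2-AFC frequency track (log2-frequency domain)."""

    initial_freq: float = 500.0
    step_start: float = 2.0 / 3.0   # octaves
    step_final: float = 1.0 / 6.0   # octaves
    step_reduction: float = 0.5     # per reversal, floored at step_final
    n_reversals_average: int = 6
    n_reversals_total: int = 8
    bounds: tuple[float, float] = (100.0, 8000.0)
    max_trials: int = 120


CU_CATEGORIES: tuple[float, ...] = (0, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50)
"""The 11 categorical-loudness response alternatives, mapped onto CU 0-50
("not heard" ... "extremely loud")."""


@dataclass(frozen=True)
class AcalosConfig:
    """Adaptive categorical loudness scaling for one 1/3-octave band."""

    band_center: float = 1000.0
    phase1_step_up: float = 10.0
    phase1_step_down: float = 15.0
    phase1_start: float = 60.0
    phase2_presentations: int = 22
    bounds: tuple[float, float] = (-10.0, 110.0)


@dataclass(frozen=True)
class HintConfig:
    """Sentence test: adaptive SRT staircase or fixed-SNR list scoring."""

    n_sentences: int = 20
    initial_snr: float = 0.0
    step_initial: float = 4.0
    step_final: float = 2.0
    initial_step_sentences: int = 4
    srt_from_sentence: int = 5
    fixed_snr: float = 4.0
    bounds: tuple[float, float] = (-25.0, 25.0)


# ---------------------------------------------------------------------------
# SIAM
# ---------------------------------------------------------------------------


def siam_deltas(t: float) -> tuple[float, float, float, float]:
    """SIAM payoff multipliers ``(hit, miss, false_alarm, correct_rejection)``.

    Values are in units of the current step size, positive toward
    "easier": a hit moves one step toward harder (-1), a miss ``t/(1-t)``
    steps toward easier, a false alarm ``1/(1-t)`` steps toward easier,
    a correct rejection leaves the track unchanged.  For ``t=0.8`` this
    gives the miss x4 / false-alarm x5 rule; for ``t=0.5`` misses match
    hits (1-up/1-down) and a false alarm doubles the step.
    """
    if not (0 < t < 1):
        raise ValueError("target probability must lie in (0, 1)")
    return (-1.0, t / (1.0 - t), 1.0 / (1.0 - t), 0.0)


def _classify(present: bool, response: bool) -> str:
    if present:
        return "hit" if response else "miss"
    return "false_alarm" if response else "correct_rejection"


def run_siam_track(
    observer: Callable[[bool, float, np.random.Generator], bool],
    config: SiamConfig,
    seed: int | np.random.Generator = 0,
) -> TrackResult:
    """Run one SIAM yes/no track.

    ``observer(stimulus_present, tracked_value, rng)`` returns the yes/no
    response.  Catch trials (no stimulus) are interleaved at
    ``config.catch_rate``.  The track terminates once
    ``discard + average`` reversals are collected (or at ``max_trials`` /
    bounds, which invalidates the run).  Signal-trial direction changes
    define reversals; the threshold is the mean of the last
    ``average_reversals`` reversal values.
    """
    rng = np.random.default_rng(seed)
    deltas = siam_deltas(config.target_prob)
    value = float(config.initial_value)
    if config.log2_domain:
        value = float(np.log2(value))
        bounds = (np.log2(config.bounds[0]), np.log2(config.bounds[1]))
    else:
        bounds = config.bounds
    step_idx = 0
    trials: list[TrialRecord] = []
    reversals: list[float] = []
    last_signal_dir = 0.0
    invalid_reason = "none"
    for i in range(config.max_trials):
        present = bool(rng.random() >= config.catch_rate)
        probe = 2.0**value if config.log2_domain else value
        response = bool(observer(present, probe, rng))
        outcome = _classify(present, response)
        mult = dict(
            hit=deltas[0], miss=deltas[1], false_alarm=deltas[2],
            correct_rejection=deltas[3],
        )[outcome]
        step = config.step_schedule[min(step_idx, len(config.step_schedule) - 1)]
        delta = config.easier_sign * mult * step
        reversal = False
        if outcome in ("hit", "miss"):
            direction = -mult  # +1 on hit (toward harder), -1 on miss
            if last_signal_dir and direction != last_signal_dir:
                reversal = True
                reversals.append(2.0**value if config.log2_domain else value)
                step_idx += 1
            last_signal_dir = direction
        trials.append(
            TrialRecord(i, present, 2.0**value if config.log2_domain else value,
                        response, outcome, delta, reversal)
        )
        if len(reversals) >= config.n_reversals:
            break
        value += delta
        if value <= bounds[0] or value >= bounds[1]:
            invalid_reason = "bounds_hit"
            value = float(np.clip(value, *bounds))
            break
    if invalid_reason == "none" and len(reversals) < config.n_reversals:
        invalid_reason = "inconsistent"
    if invalid_reason != "none":
        return TrackResult(tuple(trials), tuple(reversals), None, False,
                           invalid_reason)
    estimate = estimate_threshold(
        reversals, config.discard_reversals, config.average_reversals,
        log2_domain=config.log2_domain,
    )
    return TrackResult(tuple(trials), tuple(reversals), estimate, True)


def estimate_threshold(
    reversals: Sequence[float] | TrackResult,
    discard_n: int,
    average_m: int,
    log2_domain: bool = False,
) -> float:
    """Mean of reversal values ``discard_n .. discard_n+average_m``.

    The presets differ across tests: high-frequency audiometry discards
    four reversals and averages the next two; the noise and modulation
    tests discard two and average four.  ``log2_domain`` averages in
    log2 units (geometric mean), appropriate for frequency tracks.
    """
    if isinstance(reversals, TrackResult):
        reversals = reversals.reversal_values
    if len(reversals) < discard_n + average_m:
        raise ValueError("insufficient reversals for the requested estimate")
    vals = np.asarray(reversals[discard_n : discard_n + average_m], dtype=float)
    if log2_domain:
        return float(2.0 ** np.mean(np.log2(vals)))
    return float(np.mean(vals))


SIAM_PRESETS: dict[str, SiamConfig] = {
    # warble-tone frequency limit at fixed level: track log2-frequency,
    # higher frequency = harder
    "eAUD-HF": SiamConfig(
        target_prob=0.5, initial_value=8000.0, easier_sign=-1.0,
        step_schedule=(0.5, 0.25, 0.125, 0.125, 0.125, 0.125),
        bounds=(1000.0, 20000.0), discard_reversals=4, average_reversals=2,
        log2_domain=True,
    ),
    # tone level in 70 dB/ERB TEN: start 15 dB above expected threshold
    "eAUD-N": SiamConfig(
        target_prob=0.5, initial_value=85.0, easier_sign=1.0,
        step_schedule=(8.0, 4.0, 2.0), bounds=(0.0, 120.0),
        discard_reversals=2, average_reversals=4,
    ),
    "eAUD-S": SiamConfig(
        target_prob=0.5, initial_value=65.0, easier_sign=1.0,
        step_schedule=(8.0, 4.0, 2.0), bounds=(0.0, 120.0),
        discard_reversals=2, average_reversals=4,
    ),
    "eAUD-T": SiamConfig(
        target_prob=0.5, initial_value=75.0, easier_sign=1.0,
        step_schedule=(8.0, 4.0, 2.0), bounds=(0.0, 120.0),
        discard_reversals=2, average_reversals=4,
    ),
    # modulation level in dB ML, tracking the 80% point; higher ML = easier
    "fSTM": SiamConfig(
        target_prob=0.8, initial_value=0.0, easier_sign=1.0,
        step_schedule=(3.0, 1.5, 1.0), bounds=(-30.0, 6.0),
        discard_reversals=2, average_reversals=4,
    ),
    "S0N0": SiamConfig(
        target_prob=0.5, initial_value=85.0, easier_sign=1.0,
        step_schedule=(8.0, 4.0, 2.0), bounds=(0.0, 120.0),
        discard_reversals=2, average_reversals=4,
    ),
    "SpiN0": SiamConfig(
        target_prob=0.5, initial_value=70.0, easier_sign=1.0,
        step_schedule=(8.0, 4.0, 2.0), bounds=(0.0, 120.0),
        discard_reversals=2, average_reversals=4,
    ),
}
"""Named per-test SIAM configurations (reversal policies per test)."""


# ---------------------------------------------------------------------------
# 2-AFC frequency track (IPDfmax)
# ---------------------------------------------------------------------------


def run_2afc_frequency_track(
    observer: Callable[[float, np.random.Generator], bool],
    config: TwoAfcConfig = TwoAfcConfig(),
    seed: int | np.random.Generator = 0,
) -> TrackResult:
    """1-up/1-down 2-AFC track in log2-frequency.

    ``observer(freq, rng)`` returns True when the listener picks the
    correct (dichotic) interval.  Correct -> frequency up (harder),
    incorrect -> down.  Step sizes shrink from ``step_start`` to
    ``step_final`` octaves at each reversal and never grow; the threshold
    is the geometric mean of the last ``n_reversals_average`` reversals.
    """
    rng = np.random.default_rng(seed)
    x = float(np.log2(config.initial_freq))
    lo, hi = np.log2(config.bounds[0]), np.log2(config.bounds[1])
    step = config.step_start
    trials: list[TrialRecord] = []
    reversals: list[float] = []
    last_dir = 0.0
    invalid = "none"
    for i in range(config.max_trials):
        freq = 2.0**x
        correct = bool(observer(freq, rng))
        direction = 1.0 if correct else -1.0
        reversal = bool(last_dir and direction != last_dir)
        outcome = "hit" if correct else "miss"
        trials.append(TrialRecord(i, True, freq, correct, outcome,
                                  direction * step, reversal))
        if reversal:
            reversals.append(freq)
            step = max(step * config.step_reduction, config.step_final)
            if len(reversals) >= config.n_reversals_total:
                break
        last_dir = direction
        x += direction * step
        if x <= lo or x >= hi:
            invalid = "bounds_hit"
            break
    if invalid == "none" and len(reversals) < config.n_reversals_total:
        invalid = "inconsistent"
    if invalid != "none":
        return TrackResult(tuple(trials), tuple(reversals), None, False, invalid)
    discard = config.n_reversals_total - config.n_reversals_average
    est = estimate_threshold(reversals, discard, config.n_reversals_average,
                             log2_domain=True)
    return TrackResult(tuple(trials), tuple(reversals), est, True)


# ---------------------------------------------------------------------------
# ACALOS
# ---------------------------------------------------------------------------


def run_acalos_track(
    observer: Callable[[float, np.random.Generator], float],
    config: AcalosConfig = AcalosConfig(),
    seed: int | np.random.Generator = 0,
) -> list[tuple[float, float]]:
    """Adaptive categorical loudness scaling for one band.

    ``observer(level, rng)`` returns one of the 11 categorical CU values.
    Phase 1 brackets the dynamic range (ascending until a high-loudness
    response >= CU 40, then descending from the start level until "not
    heard"); phase 2 presents levels covering the estimated range
    uniformly, in pseudorandom order.  Returns all ``(level, CU)`` pairs.
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[float, float]] = []
    lo_bound, hi_bound = config.bounds
    # phase 1a: ascend until loud
    level = config.phase1_start
    top = None
    while level <= hi_bound:
        cu = float(observer(level, rng))
        pairs.append((level, cu))
        if cu >= 40:
            top = level
            break
        level += config.phase1_step_up
    if top is None:
        top = hi_bound
    # phase 1b: descend until not heard
    level = config.phase1_start - config.phase1_step_down
    bottom = None
    while level >= lo_bound:
        cu = float(observer(level, rng))
        pairs.append((level, cu))
        if cu <= 0:
            bottom = level
            break
        level -= config.phase1_step_down
    if bottom is None:
        bottom = lo_bound
    if not any(cu > 0 for _, cu in pairs):
        raise RuntimeError("observer never reported hearing within bounds")
    # phase 2: uniform coverage of the bracketed range, pseudorandom order
    levels = np.linspace(bottom, top, config.phase2_presentations)
    rng.shuffle(levels)
    for level in levels:
        pairs.append((float(level), float(observer(level, rng))))
    return pairs


# ---------------------------------------------------------------------------
# HINT
# ---------------------------------------------------------------------------


def run_hint(
    observer: Callable[[float, np.random.Generator], bool],
    mode: Literal["adaptive_srt", "fixed_snr"],
    config: HintConfig = HintConfig(),
    seed: int | np.random.Generator = 0,
):
    """Sentence test.

    ``observer(snr, rng)`` returns whole-sentence correctness.  In
    ``adaptive_srt`` mode a 1-down/1-up staircase (4 dB steps for the
    first sentences, 2 dB after) tracks the 50% point; the SRT is the
    mean SNR over sentences ``srt_from_sentence`` .. n plus the virtual
    next presentation.  In ``fixed_snr`` mode the score is the percent
    of sentences correct at ``config.fixed_snr``.
    """
    rng = np.random.default_rng(seed)
    if mode == "fixed_snr":
        n_correct = sum(
            bool(observer(config.fixed_snr, rng)) for _ in range(config.n_sentences)
        )
        return 100.0 * n_correct / config.n_sentences
    if mode != "adaptive_srt":
        raise ValueError(f"unknown HINT mode {mode!r}")
    snr = config.initial_snr
    presented: list[float] = []
    for i in range(config.n_sentences):
        presented.append(snr)
        correct = bool(observer(snr, rng))
        step = (config.step_initial if i < config.initial_step_sentences
                else config.step_final)
        snr += -step if correct else step
        snr = float(np.clip(snr, *config.bounds))
    presented.append(snr)  # virtual next sentence
    used = presented[config.srt_from_sentence - 1 :]
    trials = tuple(
        TrialRecord(i, True, s, True, "hit", 0.0, False)
        for i, s in enumerate(presented[:-1])
    )
    return TrackResult(trials, (), float(np.mean(used)), True)


# ---------------------------------------------------------------------------
# Repetition / validity policy
# ---------------------------------------------------------------------------


def repetition_policy(
    estimates: Sequence[float | None],
    bounds_flags: Sequence[bool] | None = None,
) -> tuple[str, float | None]:
    """Battery-wide repetition and outlier policy.

    Given the threshold estimates of the repeated runs (None for invalid
    runs), returns ``("accept", mean)`` when the estimates agree,
    ``("repeat", None)`` when any estimate lies more than three scaled
    median absolute deviations from the median, and ``("missing", None)``
    when fewer than two valid estimates exist (e.g. both runs hit a
    bound).
    """
    if bounds_flags is None:
        bounds_flags = [False] * len(estimates)
    valid = [e for e, b in zip(estimates, bounds_flags) if e is not None and not b]
    if len(valid) < 2:
        return ("missing", None)
    vals = np.asarray(valid, dtype=float)
    med = np.median(vals)
    # scaled MAD: consistent with the SD under normality
    smad = 1.4826 * np.median(np.abs(vals - med))
    if smad > 0 and np.any(np.abs(vals - med) > 3 * smad):
        return ("repeat", None)
    if smad == 0 and np.any(vals != med) and np.max(np.abs(vals - med)) > 0:
        # degenerate MAD with an actual outlier (e.g. two equal + one far)
        if len(vals) > 2:
            return ("repeat", None)
    return ("accept", float(np.mean(vals)))
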