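"""Outcome estimation: from raw responses to the 26-variable record.

This module turns raw trial data into the battery's outcome measures:

* corrected d' for the screening spectro-temporal modulation test,
* maximum-likelihood logistic fits with two free asymptotes for word
  recognition (SRT in quiet, maximum discrimination score),
* broken-stick loudness-function fits for categorical loudness scaling
  (hearing threshold level, most comfortable level, slope, dynamic
  range),
* masking release differences (temporal, spectral, binaural),
* binaural-pitch scoring, and
* the reduction of per-ear, per-frequency raw outcomes to the final
  26-variable analysis record (low/high-frequency split at 1 kHz, ears
  averaged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, least_squares
from scipy.special import expit
from scipy.stats import norm

from .observers import LoudnessFunctionParams

__all__ = [
    "ScreeningResponseSet",
    "PsychometricFit",
    "LoudnessFit",
    "OutcomeRecord",
    "BEAR3_VARIABLES",
    "dprime_screening",
    "fit_wrs_psychometric",
    "fit_loudness_function",
    "masking_release",
    "score_binaural_pitch",
    "reduce_to_bear3",
]


BEAR3_VARIABLES: tuple[str, ...] = (
    "AUD_LF", "AUD_HF", "FLFT",
    "HTL_LF", "HTL_HF", "MCL_LF", "MCL_HF",
    "DynR_LF", "DynR_HF", "Slope_LF", "Slope_HF",
    "SRT_Q", "maxDS", "SRT_N", "SScore_4dB",
    "sSTM_8", "sSTM_4k", "fSTM_8", "fSTM_4k",
    "TiN_LF", "TiN_HF", "SMR_LF", "SMR_HF", "TMR_LF", "TMR_HF",
    "IPD_fmax", "BP_20", "BMR",
)
"""Variable names of the reduced analysis table.

26 variables enter the analysis; ``fSTM_4k`` is computed but excluded
from analysis by default (most impaired listeners cannot complete the
condition), and ``sSTM_4k`` + ``fSTM_4k`` bring the full list to 28
columns of which 26 are analyzed.
"""

ANALYSIS_VARIABLES: tuple[str, ...] = tuple(
    v for v in BEAR3_VARIABLES if v not in ("fSTM_4k", "sSTM_4k")
)


# ---------------------------------------------------------------------------
# Screening d'
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreeningResponseSet:
    """Responses of one screening STM run: 10 modulated targets and 5
    unmodulated catch stimuli."""

    hits: int
    false_alarms: int
    n_modulated: int = 10
    n_catch: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.hits <= self.n_modulated):
            raise ValueError("hit count outside [0, n_modulated]")
        if not (0 <= self.false_alarms <= self.n_catch):
            raise ValueError("false-alarm count outside [0, n_catch]")


def dprime_screening(r: ScreeningResponseSet) -> float:
    """Contrast sensitivity d' with the log-linear small-sample correction.

    Rates are corrected as ``H = (h + 0.5)/(n + 1)`` before the z
    transform, which keeps d' finite at the design's ceiling (all 10
    targets hit, no false alarms -> 3.07) and floor (no yes responses at
    all -> -0.31).
    """
    h = (r.hits + 0.5) / (r.n_modulated + 1)
    f = (r.false_alarms + 0.5) / (r.n_catch + 1)
    return float(norm.ppf(h) - norm.ppf(f))


# ---------------------------------------------------------------------------
# Word-recognition psychometric fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsychometricFit:
    """Logistic fit with two free asymptotes.

    ``srt`` is the level at absolute 50% correct; ``max_score`` the upper
    asymptote in percent.
    """

    srt: float
    max_score: float
    lower_asymptote: float
    slope: float
    midpoint: float
    deviance: float
    reliable: bool = True


def _wrs_model(levels, lower, upper, mid, width):
    return lower + (upper - lower) * expit((levels - mid) / width)


def fit_wrs_psychometric(
    levels: Sequence[float],
    scores: Sequence[float],
    n_per_level: int = 25,
) -> PsychometricFit:
    """Maximum-likelihood logistic fit with free lower and upper asymptotes.

    ``scores`` are fractions correct at each presentation level (the
    battery presents 25-word lists at PTA + 40/30/20/10 dB).  The SRT is
    the level where the fitted function crosses absolute 50%; when the
    fitted function never reaches 50% within an extrapolation window the
    fit is flagged unreliable and the SRT pinned to the window edge.
    """
    levels = np.asarray(levels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if levels.size < 4:
        raise ValueError("at least four levels are required")
    k = np.round(scores * n_per_level)
    span = levels.max() - levels.min()

    # box for (lower, upper, mid, width); the guess floor of a
    # four-alternative unforced-choice task stays below ~0.3
    box = ((0.0, 0.3), (0.2, 1.0), (levels.min() - span, levels.max() + span),
           (span / 50, 2 * span))

    def nll(p):
        lower, upper, mid, width = p
        pen = 0.0
        for v, (lo, hi) in zip(p, box):
            if v < lo:
                pen += 1e4 * (lo - v) ** 2
            elif v > hi:
                pen += 1e4 * (v - hi) ** 2
        p_box = [float(np.clip(v, lo, hi)) for v, (lo, hi) in zip(p, box)]
        lower, upper, mid, width = p_box
        prob = np.clip(_wrs_model(levels, lower, upper, mid, width), 1e-6, 1 - 1e-6)
        ll = np.sum(k * np.log(prob) + (n_per_level - k) * np.log(1 - prob))
        # weak priors in the spirit of psignifit: small guess rate,
        # moderate width
        pen += 8.0 * lower**2 + 0.5 * (width / span) ** 2
        return -ll + pen

    starts = [
        (0.02, max(scores.max(), 0.5), float(np.median(levels)), span / 6),
        (0.02, max(scores.max(), 0.5), float(levels.min()), span / 6),
        (0.1, max(scores.max(), 0.5), float(np.median(levels)), span / 3),
    ]
    best = None
    for x0 in starts:
        res = minimize(
            nll, x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    lower, upper, mid, width = (
        float(np.clip(v, lo, hi)) for v, (lo, hi) in zip(best.x, box)
    )
    lower = float(np.clip(lower, 0.0, 0.3))
    upper = float(np.clip(upper, lower + 1e-3, 1.0))
    width = abs(float(width)) or 1e-3
    reliable = True
    lo_edge, hi_edge = levels.min() - span, levels.max() + span
    if lower < 0.5 < upper:
        # invert: 0.5 = lower + (upper-lower)*F  ->  F = z
        z = (0.5 - lower) / (upper - lower)
        srt = mid + width * math.log(z / (1 - z))
        if not (lo_edge <= srt <= hi_edge):
            srt = float(np.clip(srt, lo_edge, hi_edge))
            reliable = False
    else:
        srt = lo_edge if upper <= 0.5 else hi_edge
        reliable = False
    if np.all(k == n_per_level) or np.all(k == 0):
        reliable = False
    prob = np.clip(_wrs_model(levels, lower, upper, mid, width), 1e-9, 1 - 1e-9)
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(k > 0, k * np.log(k / n_per_level), 0.0) + np.where(
            n_per_level - k > 0,
            (n_per_level - k) * np.log(1 - k / n_per_level), 0.0,
        )
    deviance = float(2 * (np.sum(sat) + nll((lower, upper, mid, width))))
    return PsychometricFit(
        srt=float(srt),
        max_score=100.0 * upper,
        lower_asymptote=100.0 * lower,
        slope=float((upper - lower) / (4 * width)),
        midpoint=float(mid),
        deviance=deviance,
        reliable=reliable,
    )


# ---------------------------------------------------------------------------
# Loudness-function fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LoudnessFit:
    """Fitted categorical loudness function and its derived outcomes.

    HTL is the level at CU 2.5 (the scale's "hearing threshold"
    category boundary), MCL the level at CU 25 ("medium"), Slope the
    lower-branch slope, and DynR the level difference between CU 50
    ("extremely loud") and CU 0.5.  The CU anchors for HTL and the lower
    end of DynR are configurable because conventions differ.
    """

    htl: float
    mcl: float
    slope: float
    dyn_range: float
    params: LoudnessFunctionParams
    reliable: bool = True

    @staticmethod
    def cu_anchors() -> dict:
        return {"htl_cu": 2.5, "dynr_low_cu": 0.5, "mcl_cu": 25.0}


def fit_loudness_function(
    pairs: Sequence[tuple[float, float]],
    htl_cu: float = 2.5,
    dynr_low_cu: float = 0.5,
) -> LoudnessFit:
    """Least-squares broken-stick fit of (level, CU) pairs.

    The model is two linear branches with slopes ``m_lo`` (below CU 25)
    and ``m_hi`` (above) joined at the cut level, evaluated with the
    response clipped to [0, 50].  Derived outcomes use the unclipped
    inverse.  Data that do not span at least 20 CU are flagged
    unreliable.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.shape[0] < 8:
        raise ValueError("at least eight (level, CU) pairs are required")
    levels, cus = pairs[:, 0], pairs[:, 1]
    reliable = (cus.max() - cus.min()) >= 20.0

    def model(p, L):
        L_cut, m_lo, m_hi = p
        out = np.where(L <= L_cut, 25 + m_lo * (L - L_cut), 25 + m_hi * (L - L_cut))
        return np.clip(out, 0.0, 50.0)

    heard = cus > 0
    if heard.sum() >= 2:
        slope0, icpt = np.polyfit(levels[heard], cus[heard], 1)
        slope0 = max(slope0, 0.05)
        cut0 = (25 - icpt) / slope0
    else:
        slope0, cut0 = 0.4, float(np.median(levels))
    res = least_squares(
        lambda p: model(p, levels) - cus,
        x0=(cut0, slope0, slope0),
        bounds=((-50.0, 0.01, 0.01), (140.0, 5.0, 5.0)),
    )
    L_cut, m_lo, m_hi = (float(v) for v in res.x)
    fitted = LoudnessFunctionParams(L_cut=L_cut, m_lo=m_lo, m_hi=m_hi,
                                    response_noise_sd=0.0)
    return LoudnessFit(
        htl=fitted.level_at(htl_cu),
        mcl=fitted.level_at(25.0),
        slope=m_lo,
        dyn_range=fitted.level_at(50.0) - fitted.level_at(dynr_low_cu),
        params=fitted,
        reliable=bool(reliable),
    )


# ---------------------------------------------------------------------------
# Differences and scores
# ---------------------------------------------------------------------------


def masking_release(tin_ref: float | None, tin_cond: float | None) -> float | None:
    """Masking release: reference threshold minus condition threshold (dB).

    Positive values mean the condition unmasks the tone; negative values
    are preserved (and worth flagging downstream).  Missing inputs
    propagate.
    """
    if tin_ref is None or tin_cond is None:
        return None
    return float(tin_ref) - float(tin_cond)


def score_binaural_pitch(
    runs: Sequence[tuple[int, int]], n_dichotic: int = 10
) -> float:
    """Percent of dichotic pitch contours detected, averaged across runs.

    ``runs`` holds ``(diotic_hits, dichotic_hits)`` per repetition; only
    the dichotic contours enter the score.
    """
    if not runs:
        raise ValueError("at least one run is required")
    return float(np.mean([100.0 * d / n_dichotic for _, d in runs]))


# ---------------------------------------------------------------------------
# Reduction to the analysis record
# ---------------------------------------------------------------------------


@dataclass
class OutcomeRecord:
    """One listener's battery outcomes in the reduced analysis schema."""

    listener_id: str
    group: str = ""
    seed: int | None = None
    values: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in BEAR3_VARIABLES:
            self.values.setdefault(v, None)

    def __getitem__(self, key: str):
        return self.values[key]

    def to_row(self) -> dict:
        row = {"listener_id": self.listener_id, "group": self.group,
               "seed": self.seed}
        row.update({v: self.values[v] for v in BEAR3_VARIABLES})
        return row


def _mean_or_none(vals: Sequence[float | None]) -> float | None:
    present = [v for v in vals if v is not None]
    if not present:
        return None
    return float(np.mean(present))


def _ear_average(per_ear: Mapping[str, float | None]) -> tuple[float | None, bool]:
    """Mean of the two ears; single-ear fallback flagged."""
    vals = [per_ear.get(e) for e in ("left", "right")]
    present = [v for v in vals if v is not None]
    if not present:
        return None, False
    return float(np.mean(present)), len(present) == 1


def reduce_to_bear3(raw: Mapping, listener_id: str = "", group: str = "",
                    seed: int | None = None) -> OutcomeRecord:
    """Reduce per-ear, per-frequency raw outcomes to the analysis record.

    ``raw`` maps outcome families to nested dicts:

    * ``audiogram``: ear -> {frequency: dB HL}; averaged into AUD_LF
      (0.25-1 kHz) and AUD_HF (2-6 kHz).
    * ``flft``: ear -> Hz.
    * ``acalos``: ear -> {frequency: LoudnessFit}; HTL/MCL/DynR/Slope per
      LF and HF band.
    * ``wrs``: ear -> PsychometricFit (SRT_Q, maxDS).
    * ``hint``: ear -> {"srt_n": dB SNR, "sscore_4db": %}.
    * ``stm``: {"sSTM_8"/"sSTM_4k": d' (binaural), "fSTM_8"/"fSTM_4k":
      ear -> dB ML}.
    * ``tin``: ear -> {"N_LF": dB, "S_LF": ..., "T_HF": ...}; masking
      releases computed per ear then averaged.
    * ``ipd_fmax``: Hz; ``bp20``: %; ``bmr``: {"s0n0": dB, "spin0": dB}
      (binaural tests, no ear averaging).

    Missing entries propagate to missing variables; a variable measured
    in only one ear uses that ear and is flagged.
    """
    rec = OutcomeRecord(listener_id, group, seed)
    v, flags = rec.values, rec.flags

    lf_freqs, hf_freqs = (250, 500, 1000), (2000, 4000, 6000)

    aud = raw.get("audiogram", {})
    for band, freqs in (("LF", lf_freqs), ("HF", hf_freqs)):
        per_ear = {}
        for ear, table in aud.items():
            per_ear[ear] = _mean_or_none([table.get(f) for f in freqs])
        v[f"AUD_{band}"], flags[f"AUD_{band}"] = _ear_average(per_ear)

    v["FLFT"], flags["FLFT"] = _ear_average(raw.get("flft", {}))

    acalos = raw.get("acalos", {})
    for band, freqs in (("LF", lf_freqs), ("HF", hf_freqs)):
        for attr, name in (("htl", "HTL"), ("mcl", "MCL"),
                           ("dyn_range", "DynR"), ("slope", "Slope")):
            per_ear = {}
            for ear, fits in acalos.items():
                per_ear[ear] = _mean_or_none(
                    [getattr(fits[f], attr) if f in fits else None for f in freqs]
                )
            key = f"{name}_{band}"
            v[key], flags[key] = _ear_average(per_ear)

    wrs = raw.get("wrs", {})
    v["SRT_Q"], flags["SRT_Q"] = _ear_average(
        {e: (fit.srt if fit is not None else None) for e, fit in wrs.items()}
    )
    v["maxDS"], flags["maxDS"] = _ear_average(
        {e: (fit.max_score if fit is not None else None) for e, fit in wrs.items()}
    )

    hint = raw.get("hint", {})
    v["SRT_N"], flags["SRT_N"] = _ear_average(
        {e: d.get("srt_n") for e, d in hint.items()}
    )
    v["SScore_4dB"], flags["SScore_4dB"] = _ear_average(
        {e: d.get("sscore_4db") for e, d in hint.items()}
    )

    stm = raw.get("stm", {})
    v["sSTM_8"] = stm.get("sSTM_8")
    v["sSTM_4k"] = stm.get("sSTM_4k")
    for key in ("fSTM_8", "fSTM_4k"):
        entry = stm.get(key, {})
        if isinstance(entry, dict):
            v[key], flags[key] = _ear_average(entry)
        else:
            v[key] = entry

    tin = raw.get("tin", {})
    for band in ("LF", "HF"):
        tins, smrs, tmrs = {}, {}, {}
        for ear, table in tin.items():
            ref = table.get(f"N_{band}")
            tins[ear] = ref
            smrs[ear] = masking_release(ref, table.get(f"S_{band}"))
            tmrs[ear] = masking_release(ref, table.get(f"T_{band}"))
        v[f"TiN_{band}"], flags[f"TiN_{band}"] = _ear_average(tins)
        v[f"SMR_{band}"], flags[f"SMR_{band}"] = _ear_average(smrs)
        v[f"TMR_{band}"], flags[f"TMR_{band}"] = _ear_average(tmrs)
        for name in ("SMR", "TMR"):
            val = v[f"{name}_{band}"]
            if val is not None and val < 0:
                flags[f"{name}_{band}_negative"] = True

    v["IPD_fmax"] = raw.get("ipd_fmax")
    v["BP_20"] = raw.get("bp20")
    bmr = raw.get("bmr", {})
    if bmr:
        # BMR convention: S0N0 - SpiN0 (diotic minus dichotic threshold)
        v["BMR"] = masking_release(bmr.get("s0n0"), bmr.get("spin0"))
    return rec


def records_to_frame(records: Sequence[OutcomeRecord]):
    """Stack records into a pandas DataFrame (one row per listener)."""
    import pandas as pd

    return pd.DataFrame([r.to_row() for r in records])
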