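"""Ground-truth counterparts of battery outcomes, for recovery audits.

Every generative parameter of a :class:`~bearsim.observers.ListenerProfile`
has a matching battery outcome; this module computes the profile-implied
"true" value of each outcome so that simulated batteries can be scored by
their parameter-recovery error.  Frequency-valued outcomes (IPD_fmax,
FLFT) are compared in log2 units (octaves).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.special import logit

from .battery import BatteryConfig, run_full_battery
from .observers import ListenerProfile

__all__ = ["true_outcomes", "recovery_errors", "summarize_recovery"]

#: outcomes compared in octaves (log2 of the Hz value)
OCTAVE_OUTCOMES = ("IPD_fmax", "FLFT")


def true_outcomes(profile: ListenerProfile) -> dict[str, float]:
    """Profile-implied true value for each recoverable outcome.

    The speech and modulation truths are the points of the generative
    psychometric functions that the corresponding procedure targets: the
    absolute-50% level for the speech tests, and the 80%-yes point for
    the fast modulation test (the tracked point of its adjustment
    matrix).
    """
    t: dict[str, float] = {}
    t["AUD_LF"] = profile.band_mean("LF")
    t["AUD_HF"] = profile.band_mean("HF")
    t["FLFT"] = float(np.log2(profile.flft_true))
    for band, freqs in (("LF", (250, 500, 1000)), ("HF", (2000, 4000, 6000))):
        params = [profile.loudness[float(f)] for f in freqs]
        t[f"HTL_{band}"] = float(np.mean([p.level_at(2.5) for p in params]))
        t[f"MCL_{band}"] = float(np.mean([p.L_cut for p in params]))
        t[f"DynR_{band}"] = float(
            np.mean([p.level_at(50.0) - p.level_at(0.5) for p in params]))
        t[f"Slope_{band}"] = float(np.mean([p.m_lo for p in params]))
    sq = profile.speech_quiet
    t["SRT_Q"] = float(sq.theta + sq.sigma * logit(0.5 / (1.0 - sq.lapse)))
    t["maxDS"] = 100.0 * (1.0 - sq.lapse)
    t["SRT_N"] = float(profile.speech_noise.theta)
    t["SScore_4dB"] = 100.0 * float(
        (1.0 - profile.speech_noise.lapse)
        / (1.0 + np.exp(-(4.0 - profile.speech_noise.theta)
                        / profile.speech_noise.sigma))
    )
    p80 = (0.8 - profile.false_alarm_rate) / (
        1.0 - profile.false_alarm_rate - profile.lapse_rate)
    for key, band in (("fSTM_8", "LF"), ("fSTM_4k", "HF")):
        t[key] = float(profile.stm_threshold[band]
                       + profile.stm_sigma * logit(p80))
    for band in ("LF", "HF"):
        t[f"TiN_{band}"] = profile.tin_true[f"N_{band}"]
        t[f"SMR_{band}"] = profile.tin_true[f"N_{band}"] - profile.tin_true[f"S_{band}"]
        t[f"TMR_{band}"] = profile.tin_true[f"N_{band}"] - profile.tin_true[f"T_{band}"]
    t["BMR"] = profile.s0n0_true - profile.spin0_true
    t["IPD_fmax"] = float(np.log2(profile.ipd_fmax_true))
    t["BP_20"] = 100.0 * profile.bp_detect_prob
    return t


def recovery_errors(
    cohort: Sequence[ListenerProfile],
    config: BatteryConfig = BatteryConfig(),
) -> dict[str, list[float]]:
    """Signed recovery error (recovered - true) per outcome over a cohort.

    Missing outcomes are skipped (they carry no error).  Octave-valued
    outcomes are differenced in log2 units.
    """
    errors: dict[str, list[float]] = {}
    for profile in cohort:
        record, _, _ = run_full_battery(profile, config)
        truths = true_outcomes(profile)
        for key, true_val in truths.items():
            measured = record.values.get(key)
            if measured is None:
                continue
            if key in OCTAVE_OUTCOMES:
                measured = float(np.log2(measured))
            errors.setdefault(key, []).append(float(measured) - true_val)
    return errors


def summarize_recovery(errors: Mapping[str, Sequence[float]]):
    """Median absolute and signed error per outcome (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for key, e in errors.items():
        e = np.asarray(e, dtype=float)
        rows.append({
            "outcome": key,
            "n": e.size,
            "median_abs_error": float(np.median(np.abs(e))),
            "median_error": float(np.median(e)),
        })
    return pd.DataFrame(rows).set_index("outcome")
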