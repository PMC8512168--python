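"""Run one SIAM yes/no track for a simulated observer.

The single-interval adjustment matrix steers the tracked tone level with
payoff multipliers derived from the targeted hit probability; catch
trials police the observer's criterion.  Here an unbiased observer with
threshold 70 dB (2-dB spread, 5% false alarms) is tracked with the
tone-in-noise preset; the estimate should land within a final step or
two of 70 dB.
"""

from bearsim.adaptive import SIAM_PRESETS, run_siam_track, siam_deltas
from bearsim.observers import PsychometricParams, psychometric_prob

params = PsychometricParams(theta=70.0, sigma=2.0, gamma=0.05, lapse=0.02)


def observer(present, value, rng):
    if not present:
        return rng.random() < 0.05  # false alarm on a catch trial
    return rng.random() < psychometric_prob(value, params)


print("payoff multipliers (hit, miss, false alarm, correct rejection):")
print(f"  target 50%: {siam_deltas(0.5)}")
print(f"  target 80%: {siam_deltas(0.8)}")

track = run_siam_track(observer, SIAM_PRESETS["eAUD-N"], seed=1)
n_catch = sum(not t.stimulus_present for t in track.trials)
print(f"\ntrack: {len(track.trials)} trials ({n_catch} catch), "
      f"{len(track.reversal_values)} reversals")
print("reversal values:", [round(v, 1) for v in track.reversal_values])
print(f"threshold estimate (discard 2, average 4): "
      f"{track.threshold_estimate:.2f} dB  [true 50% point: 70 dB]")
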