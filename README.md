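# bearsim

A simulatable re-implementation of the BEAR auditory test battery: a
clinical battery of ten psychoacoustic tests designed to characterize
hearing deficits beyond the pure-tone audiogram, covering audibility,
loudness perception, speech perception in quiet and in noise,
spectro-temporal processing, and binaural processing abilities.

`bearsim` is aimed at hearing researchers and methods developers who
want to exercise the battery end-to-end *without human subjects*: every
stimulus is synthesized from a parameter record, every adaptive
procedure is driven by a simulated listener with known generative
parameters, and the study-level statistics (test–retest reliability,
correlation structure, factor analysis) run on the resulting outcome
tables. That makes properties measurable that are invisible in human
data — convergence and bias of the tracking procedures, parameter
recovery of the fitted outcomes, and the behavior of the exploratory
statistics under a known ground truth.

## What is implemented

- **Stimuli** (`bearsim.stimuli`) — warble tones
  `wt(t) = sin(2π f_c t + (f_c f_e / f_r) sin(2π f_r t))` (excursion
  f_e = 4.3%, rate f_r = 4 Hz), threshold-equalizing noise (TEN) with
  constant power per ERB, frequency-shifted (1.1 f_tone) and 4-Hz
  modulated variants, spectro-temporal ripple noise with depth
  m = 10^(ML/20), Huggins-type dichotic noise with interaural phase
  contours, and diotic/dichotic four-tone sequences — plus the signal
  analysis to verify each (instantaneous frequency, per-ERB band power,
  cross-spectral phase, ripple contrast).
- **Adaptive procedures** (`bearsim.adaptive`) — SIAM yes/no tracks with
  catch trials and payoff multipliers (−1, t/(1−t), 1/(1−t), 0) for
  target probability t; 1-up/1-down 2-interval frequency tracking in
  log2 units (2/3 → 1/6 octave steps); adaptive categorical loudness
  scaling; sentence staircases; and the battery-wide repetition/outlier
  policy (3 scaled MADs).
- **Simulated listeners** (`bearsim.observers`) — psychometric response
  models with false-alarm and lapse rates, broken-stick loudness
  functions, and a cohort generator whose audiograms span the standard
  audiograms N1–N4 with two partially independent latent severities
  (low- and high-frequency), loudness recruitment linked to local loss,
  speech-in-noise and spectro-temporal deficits linked to
  high-frequency loss, and binaural abilities independent of the
  audiogram.
- **Outcomes** (`bearsim.outcomes`) — corrected d′ = z(H) − z(F) for the
  screening modulation test, maximum-likelihood logistic fits with two
  free asymptotes (SRT_Q, maxDS), loudness-function fits (HTL, MCL,
  Slope, DynR), masking releases (TMR, SMR, BMR), binaural-pitch
  scoring, and the reduction to the 26-variable analysis record
  (LF/HF split at 1 kHz, ears averaged).
- **Analysis** (`bearsim.analysis`) — ICC(2,1) absolute agreement,
  SEM = SD·√(1−ICC), Spearman matrices with significance masks, Horn's
  parallel analysis, and ML + varimax factor analysis.
- **Battery** (`bearsim.battery`) — orchestration per listener and per
  cohort, bit-reproducible from a master seed, with a thin CLI
  (`bearsim synth-cohort | simulate | analyze | reliability | read-bear3`).

## Worked example

Run one tone-in-noise track for an unbiased simulated observer
(threshold 70 dB, 2-dB spread, 5% false alarms):

```bash
python examples/run_adaptive_track.py
```

```
payoff multipliers (hit, miss, false alarm, correct rejection):
  target 50%: (-1.0, 1.0, 2.0, 0.0)
  target 80%: (-1.0, 4.000000000000001, 5.000000000000001, 0.0)

track: 14 trials (2 catch), 6 reversals
reversal values: [69.0, 77.0, 71.0, 73.0, 67.0, 71.0]
threshold estimate (discard 2, average 4): 70.50 dB  [true 50% point: 70 dB]
```

The payoff rows are the adjustment-matrix step multipliers: at the 80%
target a miss moves the track 4 steps toward easier and a false alarm
("caught" on a catch trial) 5 steps; at the 50% target the procedure
behaves like a 1-up/1-down staircase whose step doubles after a false
alarm. The track estimate (70.5 dB) is the mean of the last four
reversal values and sits within a final step of the observer's true
threshold — which, in threshold-equalizing noise at 70 dB/ERB, is the
noise level itself.

The other examples cover stimulus verification
(`synthesize_stimuli.py`), a full single-listener battery with measured
vs. true outcomes side by side (`simulate_listener.py`), test–retest
reliability tables (`cohort_reliability.py`), and the cohort-level
correlation clusters and factor solution (`exploratory_analysis.py`).

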