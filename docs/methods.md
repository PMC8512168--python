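# Methods

This note documents the models behind `bearsim`: what each simulated
test assumes, the parameters that matter, what the cohort generator
does and does not emulate, and the numerical choices made where the
battery's published description leaves the design open.

## Stimulus models

**Warble tone.** The frequency-modulated tone is rendered directly from
its phase function, `sin(2π f_c t + (f_c f_e / f_r) sin(2π f_r t))`, so
the instantaneous frequency is `f_c (1 + f_e cos(2π f_r t))` and the
*peak* fractional excursion equals `f_e` (default 0.043; the
peak-vs-peak-to-peak reading of "excursion" is ambiguous in the source
material — we take peak, which the phase term implies). Defaults: 4-Hz
rate, 500-ms tones, 50-ms raised-cosine ramps, 48 kHz sampling.

**Threshold-equalizing noise (TEN).** Gaussian noise confined to a
one-octave band whose spectral density is weighted by 1/ERB(f), with
ERB(f) = 24.7·(4.37 f/1000 + 1). This makes the power falling into any
ERB-wide window constant across the band — the property that places a
normal listener's masked tone threshold at the per-ERB noise level. The
rendered waveform is scaled so the measured power in one ERB at the
tone frequency equals the requested level (±0.5 dB for multi-second
realizations; windows overlapping the band edge necessarily read low).
The spectral condition shifts the band center to 1.1 × tone frequency;
the temporal condition applies sinusoidal amplitude modulation at 4 Hz.
The modulation depth (1.0) and waveform (sinusoidal) are this package's
defaults — listening "in the dips" requires deep modulation — and are
configurable.

**Ripple (STM) noise.** A dense sum of log-spaced random-phase tones,
each amplitude-modulated along the ripple trajectory
`1 + m sin(2π(Ω log2(f/f_lo) + w t) + φ)` with `m = 10^(ML/20)`.
Defaults Ω = 2 cycles/octave and w = 4 Hz (downward), matching the
low-frequency condition style of the literature the test derives from;
the source text does not fix them. `ripple_contrast` demodulates the
log-spectrogram along the known trajectory; it is used in tests as a
monotone witness of `m`, not as a calibrated estimator.

**Dichotic (Huggins) noise.** Flat-spectrum noise identical in the two
channels except inside transition bands (default width 16% of the
contour frequency) around dichotic contours, where the right channel's
phase is offset by the interaural phase difference (default π). Diotic
contours are rendered as a +12 dB narrow-band increment in both
channels — a monaurally detectable tonal prominence. The clinical
test's actual diotic rendering is unpublished; this choice is
documented, configurable, and makes no fidelity claim.

## Adaptive procedures

**SIAM.** The yes/no single-interval adjustment matrix applies step
multipliers (hit, miss, false alarm, correct rejection) =
(−1, t/(1−t), 1/(1−t), 0) in units of the current step, signed toward
"easier". At t = 0.8 this is the miss ×4 / false-alarm ×5 rule; at
t = 0.5 it behaves as a 1-up/1-down staircase whose step doubles after
a false alarm. At the targeted hit probability the expected signal-trial
step is zero, which is what makes the track converge on the t-point of
the observer's psychometric function. Catch trials are interleaved at
20% (unstated in the source; configurable). Reversal policies are
presets, not hard-coded: the high-frequency audiometry preset discards
four reversals and averages the next two; the tone-in-noise and
modulation presets discard two and average four. Tracks that reach a
bound, or fail to collect the required reversals, are invalid. Tracked
values stay continuous; rounding happens only in reports.

Initial values (unstated in the source): tone-in-noise tracks start
15 dB above the expected threshold, the frequency-limit track at 8 kHz,
the fast modulation track at 0 dB modulation level. Step schedules
halve toward a 2-dB final step (level tracks) or an eighth-octave final
step (frequency track).

**Frequency track for the interaural-phase limit.** 1-up/1-down in
log2-frequency with steps shrinking from 2/3 to 1/6 octave per
reversal; the threshold is the geometric mean of the last six
reversals, and the battery averages two runs in log2 units. The track
steps on the listener's *detection report* (positive response), not on
two-interval correctness. This distinction matters: above the phase
limit a listener's forced choice is a fair coin, so a staircase driven
by correctness has zero drift there and random-walks arbitrarily high,
while the detection report falls to the false-alarm rate and anchors
the track at the limit. Simulations with a hard frequency limit confirm
the anchored variant recovers the limit to well within 1/6 octave while
the correctness-driven variant is biased high by several final steps.

**Categorical loudness scaling.** Phase 1 brackets the dynamic range
(ascend in 10-dB steps until a response ≥ 40 CU, descend in 15-dB steps
until "not heard"); phase 2 places 22 presentations uniformly across
the bracketed range in pseudorandom order. This is a simplification of
the published level-placement rule; the package's claim is calibrated
accordingly — outcomes are validated by loudness-fit parameter
recovery, not by procedural fidelity.

**Sentence test.** Speech materials are abstracted: a sentence at a
given SNR is a Bernoulli draw from the listener's speech-in-noise
psychometric function (no lexical modeling). The adaptive mode is a
1-down/1-up whole-sentence staircase, 4-dB steps for the first four
sentences then 2 dB, with the SRT the mean SNR of sentences 5..20 plus
the virtual 21st; the fixed-SNR mode scores 20 sentences at +4 dB.

**Repetition policy.** Threshold tests run twice; a run is an outlier
if it lies more than three scaled median absolute deviations
(1.4826·MAD) from the median of the runs, triggering extra runs (up to
two); fewer than two valid, in-bounds runs makes the outcome missing.

## Outcome estimation

**Screening d′.** d′ = z(H) − z(F) with the log-linear correction
H = (h + 0.5)/(n_mod + 1), F = (f + 0.5)/(n_catch + 1). The correction
was chosen because it reproduces both printed anchors of the
10-modulated/5-catch design simultaneously: ceiling 3.07 and floor
−0.31 ≈ −0.3.

**Word recognition.** Maximum-likelihood logistic fit with two free
asymptotes on 25-word scores at PTA + {10, 20, 30, 40} dB. The guess
floor is bounded at 0.3 and weakly penalized (the task is a
four-alternative *unforced* choice, so the effective guess rate is well
below 25%), and a mild width prior stabilizes the four-point design;
multi-start Nelder-Mead avoids local optima. SRT_Q is the level at
absolute 50% correct (not the asymptote midpoint); maxDS is the upper
asymptote. Fits on ceiling/floor data or with the 50% crossing outside
an extrapolation window are flagged unreliable.

**Loudness function.** Least-squares broken-stick fit: two slopes
joined at the cut level (CU 25), response clipped to [0, 50]. HTL is
the level at CU 2.5 (the conventional threshold anchor), MCL the level
at CU 25, Slope the lower-branch slope m_lo (its magnitude matches the
published normal-hearing range ≈ 0.33 CU/dB), and DynR the level
difference between CU 50 and CU 0.5. The CU-0.5 lower anchor for DynR
and the CU-2.5 anchor for HTL follow different conventions in the
source description; both anchors are arguments of
`fit_loudness_function` so either reading can be reproduced.

**Reduction.** Frequency-specific outcomes are averaged into LF
(≤ 1 kHz: 0.25/0.5/1 kHz) and HF (> 1 kHz: 2/4/6 kHz) bands, monaural
tests ear-averaged, missing values propagated (single-ear values are
used and flagged). The full record has 28 columns; the analysis set is
26, excluding the two 4-kHz modulation variables (the fast 4-kHz
condition is rarely completable, mirroring the clinical experience, and
the screening 4-kHz score is kept out of the analysis set for symmetry).

## The simulated cohort

A listener is a set of generative parameters, not an auditory model:
no cochlear mechanics, no cognition. The cohort generator emulates the
*statistical structure* a profiling battery is designed to expose:

- **Audiograms** interpolate the IEC 60118-15 standard audiograms N1–N4
  (8 kHz extrapolated from the published 4→6 kHz slope) with *two*
  latent severities — one for the low-frequency side, one for the
  high-frequency side — correlated at 0.3 by default, plus 5-dB
  per-frequency jitter. Two severities, not one, is what produces the
  separate low- and high-frequency correlation clusters in the outcome
  table; a single severity collapses them into one factor.
- **Loudness recruitment**: the lower-branch slope steepens with the
  local hearing loss (0.33 CU/dB at no loss, ≈ 0.8 at 60 dB), the upper
  branch starts at 1.0 CU/dB, and the CU-2.5 point is anchored at the
  audiometric threshold. These coefficients reproduce the published
  normal-hearing reference region (MCL ≈ 70 dB, DynR ≈ 99 dB, Slope
  0.27–0.44 CU/dB) and the impaired high-frequency dynamic range
  (≈ 50 dB) without further tuning.
- **Speech**: the quiet SRT sits ~10 dB above the PTA (so the fixed
  presentation design brackets it), the noise SRT worsens with
  high-frequency loss, and the maximum discrimination score falls
  through a lapse rate growing with high-frequency loss.
- **Spectro-temporal and masking-release deficits** grow with
  high-frequency loss; tone-in-noise reference thresholds sit near the
  70 dB/ERB noise level with a small efficiency penalty.
- **Binaural parameters** (phase limit, binaural-pitch detection,
  binaural masking release ≈ 15 dB) are drawn independently of the
  audiogram, reflecting the empirical finding that binaural abilities
  are not predicted by it.
- **Response noise**: 5% false alarms, 2% lapses, 2-dB detection
  spread, 3-CU loudness response noise. A `noise_free` switch collapses
  all of these to (near) zero for reliability baselines.

What passing tests show, and what they do not: recovery and reliability
results demonstrate that the *procedures and estimators* are unbiased
and consistent under these generative assumptions; they say nothing
about physiological validity, real listeners' criterion drift,
learning, or attention, none of which are modeled. The high missing
rate of the fast 4-kHz modulation condition emerges naturally (tracks
that demand more than full modulation are invalid), qualitatively
matching clinical experience, but missingness probabilities are
population-dependent and are reported descriptively, never asserted.

## Analysis stage

ICC is the two-way random-effects, absolute-agreement, single-measure
form, computed from the ANOVA mean squares; absolute agreement was
chosen because session biases should cost reliability. SEM is the
pooled between-subject SD times √(1 − ICC). Spearman matrices use
pairwise deletion and a t-approximation for p-values (masked at
p < 10⁻⁵). Parallel analysis compares the observed correlation
eigenvalues against the 95th percentile of 500 standard-normal
surrogate tables and counts the leading run of exceedances. Factor
extraction is maximum likelihood (statsmodels) with varimax rotation;
factors are ordered by explained variance (sum of squared loadings /
number of variables), sign-oriented so the dominant loading is
positive, with loadings above 0.65 reported as salient and Heywood
cases flagged.

## Problem sizes and tolerances

The shipped simulations use the sizes the package's own validation
needs: 100 tracks for staircase-convergence checks, 50-listener cohorts
for recovery (median absolute error ≤ 3 dB for threshold-type outcomes,
≤ 1/6 octave for the phase limit, ≤ 0.05 CU/dB for loudness slopes),
15-listener cohorts for reliability baselines, and 20 replicates for
the factor-count check. Waveform-level verifications use 2–10 s
realizations at 48 kHz. Numerical tolerances in the tests reflect
measurement resolution (e.g. ±0.5 dB for per-ERB levels from finite
realizations, ±2% for instantaneous-frequency analysis), not model
uncertainty.

## Known limitations

- Stimulus rendering and the adaptive simulations are decoupled: tracks
  feed the observer the tracked value directly rather than rendering
  audio per trial. The stimuli module is verified independently.
- No hearing-level-to-SPL calibration beyond an identity table;
  transducer reference levels are out of scope.
- The diotic-contour rendering of the binaural-pitch stimulus is a
  documented invention (the clinical implementation is unpublished).
- Phase-2 level placement in loudness scaling is a uniform-coverage
  simplification.
- Bayesian adaptive procedures are not implemented; the observer
  interface leaves room for them.
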