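# Methods

## The analysis model

The pipeline treats a head-fixed go/no-go training experiment as two
nested processes: task acquisition across daily sessions (learning) and
motivation-state fluctuations within sessions, on the scale of tens of
trials. States are defined operationally from smoothed behavior, never
from a latent-variable model: a 50-trial centered moving mean (1-trial
steps, computed independently within each session so no smoothing
crosses a day boundary) is applied to whole-trial lick rate and binary
correctness, the smoothed vectors are concatenated across days per
mouse, and two per-mouse thresholds binarize them:

* **licking axis** — a trial-count histogram with exactly 100
  equal-width bins over the observed range; trials at or below the
  upper edge of the second bin are *low/no licking*;
* **correctness axis** — trials at or above the mouse's 75th sample
  quantile (linear interpolation, ties inclusive) are *good
  performance*. The quantile is per mouse, never pooled, because
  correctness distributions differ in range, skew and bimodality
  between animals.

Merging the axes gives three states with good performance taking
precedence: *attentive* (good), *disengaged* (low/no licking, not
good), *persistent* (moderate/high licking at chance). The
(low/no licking, good) combination should not occur in well-behaved
data; the labeler counts it and warns above 1%.

**Edge rule for the moving mean.** The smoothing window is centered
with shrinking edges: near a session boundary the window truncates
rather than padding, so output length equals input length, every trial
is an unweighted mean of real trials, and sessions stay independent.

## State decoding

Per mouse, the decoder consumes the eight smoothed nonperformance
variables. To break the autocorrelation the 50-trial smoothing
introduces, rows (trials) are shuffled in 25-trial blocks — labels
travel with their rows — and the table is split 1:1; a bagged ensemble
of 30 fully grown decision trees (no depth limit, bootstrap resampling
at full training-half size) scores the held-out half, roles are
swapped, and the two held-out score sets are recombined in
chronological order, so each trial is scored exactly once per run.
Class scores are the ensemble's vote fractions. ROC analysis is
one-vs-rest; a group of iterations (default 100) with random predictor
pools of a given size pools all (score, label) pairs into one curve
("pooled" mode; per-iteration averaging is available). The
AUC-vs-pool-size curve is fit by nonlinear least squares to
`y = a − b·exp(−k·x)` with multi-start initial rates; the p-value for
`k` uses the Jacobian-based covariance (asymptotic normal
approximation). Flat or non-identifiable curves are flagged with no
p-value.

Controls reproduce the standard battery: cross-mouse prediction (all
ordered train→test mouse pairs, size-matched held-out sets), trial-order
shuffling (rows only; decodability preserved), full shuffling (rows
plus every predictor column independently; AUC falls to chance),
physiologic vs neurophysiologic predictor subsets, forced
inclusion/exclusion of one variable, and leave-one-predictor-out
regressions — OLS on smoothed correctness without intercept
(predictors z-scored) and multinomial regression on the states with
each state rotated through the reference slot. Friedman tests compare
real against shuffled-response t-statistic distributions across
predictors; the multinomial branch is tested per state because
coefficients mirror across reference rotations and would cancel when
pooled.

## Training progression and laminar profiles

Eight state × outcome subcategories are retained (persistent hits and
false alarms; all four attentive outcomes; disengaged correct
rejections and misses) — unattended persistent trials and attended
disengaged trials are rare by construction and excluded. Each
subcategory maps chronologically onto 99 contiguous blocks, sizes as
equal as possible with the remainder assigned to the earliest blocks
(`numpy.array_split` semantics), grouped into early/mid/late stages of
33 blocks. Peristimulus traces use 80 bins over [−1, +4] s (bin width
62.5 ms, chosen so the repeated-measures dimension has 79 degrees of
freedom); lick rates are raw binned rates, wheel speed is
mean-subtracted by its own prestimulus mean (z-scoring exaggerates
small peaks in low-motricity trials), and eye signals are z-scored by
their prestimulus mean and SD with an SD floor of 1e-6 of the trace
range.

The stage comparison is a split-plot two-way ANOVA: stage is a
between-units factor, trial blocks (pooled across mice) are the units,
and peristimulus bins (or laminar channels) are the repeated-measures
axis. The decomposition is implemented directly as vectorized sums of
squares — the 1,000-run null calibration in the test suite needs a
fast path — and is verified in the tests against both a hand-computed
sums-of-squares oracle and `pingouin.mixed_anova`. Tukey HSD across the
three stages runs per bin/channel; computing the studentized-range
p-value per position is comparatively slow, so the per-position post
hocs are optional in the batch drivers.

Laminar maps cover [−0.05, +0.25] s around stimulus onset on the 45
topmost channels (20 µm spacing; depth 0 mm at the topmost analysed
channel, which makes the ~0.9 mm span and the quoted depth-band edges
self-consistent). CSD is the discrete second spatial difference (edge
channels filled by replicating the nearest interior value, preserving
the 45-channel profile length; conductivity and spacing constants are
omitted because profiles are z-scored and min–max normalized, so units
cancel), z-scored per channel, smoothed over 5 channels and 20 ms. MUA
power sums a per-channel spectrogram (4 ms window, 50% overlap) over
500–5,000 Hz, z-scored per channel and smoothed over 10 ms with no
spatial smoothing; maps are computed per trial and averaged within
blocks, since MUA is not phase-locked. Depth profiles are the mean
absolute map over 0–100 ms post-stimulus, detrended with a centered
22-channel moving mean and min–max normalized to [0, 1]; constant
profiles return 0.5 everywhere with a degeneracy flag. The deep-MUA
landmark check requires a prominent local maximum within ±0.1 mm of
0.6 mm; mice failing it are excluded from laminar analysis but keep
contributing channel-averaged features. Somatotopy selection picks the
whisker pair maximizing mean |CSD| over channels × 0–250 ms, with
lexical tie-breaking (flagged).

## The synthetic generator

`motistate.synth` emulates the study conditions: 5 virtual mice,
12–14 daily sessions of 500 trials, trial epochs of 1 s prestimulus,
200 ms stimulus, 1.8 s answer and 2 s intertrial (10 s after false
alarms), and a pseudorandom go/no-go sequence built by re-flipping any
draw that would create a fourth consecutive repetition (approximately
balanced counts; exact balance is not enforced).

Latent states follow a semi-Markov chain: geometric dwell times with a
150-trial mean, forced switches at dwell expiry, and transition
weights biased by within-session phase (disengagement probability
0.08 + 0.55·phase²) and training day (attentive weight 0.12 +
learning_rate·(day−1), default learning rate 0.035/day, capped at
0.65). The dwell clock carries across session boundaries — so the
empirical run-length distribution matches the configured mean without
truncation bias — except that a session never *starts* disengaged
(mice begin sessions alert; a carried disengaged stretch is re-drawn
at the first trial of a day). Outcomes come from state-dependent
response probabilities: persistent responds at 0.85 regardless of
type, attentive at 0.95 (go) / 0.10 (no-go), disengaged at 0.02.

Each nonperformance variable couples to the state through a per-state
mean, a Gaussian per-trial spread and a per-state per-day drift; the
defaults place prestimulus licking at 2.5/0.02/1.0 Hz
(persistent/disengaged/attentive), wheel speed at 6/0.5/3 cm/s with a
+0.15 cm/s·day learning drift, pupil diameter at 1.10/0.75/1.00 mm,
eyelid aperture at 2.60/2.10/2.50 mm, PSS at −1.0/−1.6/−1.1 (steeper
in quiescence, +0.02/day), evoked LFP at −55/−35/−60 µV with the
persistent dipole attenuating by 1.5 µV/day, and MUA baseline/burst
amplitudes rising modestly with training (the deep burst most strongly
in attentive states). Streams are rendered from these tendencies:
inhomogeneous Poisson licks with consummatory bursts after hits; a
wrapping encoder voltage (modulo the stated 36 cm circumference — note
the source protocol quotes a 13 cm wheel diameter, which would imply
~40.8 cm; the stated 0–36 cm rescaling is taken as authoritative)
whose speed acquires a learned anticipatory ramp before the stimulus
and a post-stimulus halt in late-training false alarms; keypoint
octagons (regular octagons with top/bottom vertices jitter-free so the
configured diameter is exact); LFP epochs as spectrally synthesized
1/f^α noise (α = −PSS) plus a stimulus-locked transient with a
common-mode component (visible to channel-averaged evoked LFP) and a
sink/source dipole pair (visible to CSD) at a configurable depth; raw
epochs as broadband noise with a post-stimulus burst whose depth
profile peaks at the 0.6 mm landmark.

**What the generator does not emulate** — and hence what passing tests
do not show about real recordings: electromyographic artifacts,
correlated noise across channels, oscillatory (non-aperiodic) LFP
structure, pupil light reflexes, video tracking errors, and any
within-state temporal microstructure beyond the Poisson/Gaussian
tendencies. Results on synthetic data validate the machinery, not the
biology.

## Problem sizes and numerical choices

Electrophysiology is synthesized only within per-trial epochs
([−1.0, +0.25] s around stimulus onset) at 1,250 Hz (LFP) and 20 kHz
(raw): every analysis consumes prestimulus or peristimulus windows, so
continuous multichannel traces would add volume without information.
The encoder is synthesized at 100 Hz (speed extraction is
rate-agnostic). The test suite and the acceptance script run on
reduced probes (8–45 channels) and reduced session counts, with
landmark and dipole depths placed inside the reduced probe span; the
shuffle-control benchmark uses the full 14 × 500-trial design with an
8-channel probe, since its decoded features are channel-averaged. All
randomness flows through a single seed fanned out deterministically
per mouse/session/stream.

PSS fitting interpolates the Welch grid onto 100 log-spaced centers in
1–100 Hz before the log-log line fit (the resampling scheme is
otherwise underdetermined); MUA band power interpolates onto 500 Hz
centers and sums. Evoked MUA uses a 50 ms Welch window because the
protocol's 0.5 s window cannot fit inside the 200 ms stimulus. Lick
counting uses half-open [start, end) windows to avoid double counting;
whole-trial lick rates cover the 5 s trial core, excluding punishment
extensions. Eye trials with no valid frames are imputed with the
session median and flagged, because the classifier requires complete
rows. Whole-trial wheel speed is a signed mean — backward running is
informative and would be destroyed by rectification.

## Known limitations

* The split-plot ANOVA treats trial blocks as independent units;
  blocks from one mouse share animal-level variance, so with few mice
  the stage test is anti-conservative for biological claims (the
  degrees of freedom printed by analogous published tables cannot be
  reconstructed unambiguously from blocks × mice × stages; the
  blocks-as-units convention is used and stated).
* Per-trial z-scoring of CSD/MUA maps equalizes channel variance, so
  single-trial profiles are noisy; depth structure emerges from block
  averages (≥ ~20 trials per block at the default noise levels).
* The labeler's 75th-quantile rule fixes the attentive fraction near
  25% of trials per mouse by construction; agreement with the
  generator's latent states (Cohen's κ ≳ 0.7 at defaults) is bounded
  by this design, not by the decoder.
* No spike sorting, layer assignment or single-trial state models are
  implemented; these are out of scope by design.
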