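# Methods

This package re-implements, end to end, the analysis of premotor
motor-equivalence (Meq) neurons — cells that fire phasically before and
during movements of either the eye or the hand — together with a synthetic
task generator that stands in for the unavailable recordings.  This note
documents the models, the estimators, the places where the design was
genuinely open, and what the synthetic data can and cannot show.

## The task and the synthetic generator

`meq.synth` emulates a center-out task: after a fixation period and an
effector instruction, a target appears in one of 8 directions (45° apart,
0° = rightward, counter-clockwise) at 10° or 20° eccentricity; a go cue
releases a movement of the eyes, the hand-driven cursor, or both.  Epoch
durations (fixation 200–300 ms, instruction 200–300 ms, delay 300–1200 ms),
sampling rates (eye 1000 Hz, cursor 666 Hz), the 1.5° fixation/target
windows and the movement deadlines (600/1200 ms) follow the task layout the
analysis was built for.

**Kinematics.** Saccade speed profiles are raised-cosine bells, hand
movements minimum-jerk — both smooth and analytically integrable, so the
profile support can be solved (Brent's method, closed form for minimum
jerk) such that the *detected* durations under the onset rules below hit
the calibration points: 45/58 ms for 10°/20° saccades, 198/257 ms for hand
movements.  The generator records the analytic threshold-crossing times as
ground truth.

**Reaction times.** A latent command time C ~ N(200, σ_C²) is drawn per
trial; each effector's onset is C plus independent Gaussian noise (plus the
81-ms eye→hand offset).  The noise scales are solved from two constraints:
the eye–hand interval SD is 33 ms, and corr(C, effector onset) = ρ (default
0.7).  This makes the eye–hand onset correlation converge to ρ² ≈ 0.49 —
the shared-command account of why effector onset correlations hover near
0.5.  The marginal saccade RT mean (200 ms) is a free parameter chosen as a
typical primate visually guided latency; only the interval statistics are
constrained by the reported data.

**Spikes.** Each archetype defines, per condition, a preferred direction,
a field width (2/√k in degrees, default near 160°), a peak rate (drawn so
burst rates span the reported 18–166 spikes/s), a baseline (5–15 spikes/s),
a burst duration and a discharge lead (70 ms before saccades, 152 ms before
hand movements).  The rate envelope is baseline + peak × von-Mises
direction gain × a rectangular burst window; spikes are drawn by Poisson
thinning.  Burst onset follows the archetype's locking rule: locked to the
saccade, to the hand movement, or to the shared command (which yields
correlations with both effectors).  In single-effector trials a cell not
locked to the executed effector still bursts ahead of the movement on
average — its burst is centered at the *expected* movement time minus the
configured lead — but trial-to-trial it tracks only the go cue, which is
exactly the structure the onset-jitter analysis is designed to detect.
"Mixed"-field cells drift their preferred direction from the eye pd to the
hand pd across −30…+120 ms around saccade onset.  One RNG stream per
(session seed, trial, cell) makes any trial independently reproducible.

`make_reference_population` mirrors the packaged 55-row reference
classification table row by row (27 invariant / 10 eye / 8 hand / 6
intermediate / 4 mixed on-direction cells; onset locks 36 both / 15 eye /
4 hand).  Two printed label combinations are unrealizable (direction-
dependent burst duration needs distinct eye/hand pds) and are mapped to
their nearest realizable archetype.

## Kinematic event detection

Speed is computed by central differences and a short boxcar (7 samples for
the eye, 5 for the hand; results on clean traces are insensitive to ±2
samples).  Saccade onset is the first crossing of 20 deg/s; hand onset the
first crossing of 1% of the trial's peak speed, with the peak taken in the
go-cue→deadline window.  Hand offset (needed for durations, unspecified
upstream) is the first time speed stays below 5% of peak for ≥50 ms.
Movement direction/amplitude come from the onset→offset displacement.

## Spike-train measures

The instantaneous rate is R_n = 5/(t_{n+3} − t_{n−2}): the inverse of the
running average of five consecutive inter-spike intervals, attached at
spike times and linearly interpolated to a 1-ms grid.  On a homogeneous
Poisson train the *mean* of R_n is biased to 5λ/4 (Jensen), while the
median is within a few percent of λ; this is documented estimator behavior
and is not corrected.  Baseline mean μ and SD come from the reference
period (300 ms ending at the go cue); a degenerate SD falls back to the
pooled across-trial SD, then to the Poisson-count SD.

**Discharge onset** is the first time the normalized rate exceeds 2 SD and
stays there ≥10 ms (the persistence criterion replaces the manual onset
checks such analyses traditionally relied on).  Because R_n interpolates
across sparse background spikes, that crossing carries a ±1–2 background-ISI
smear, so a spike-level refinement then advances the onset to the first
spike whose own interval, three-interval and five-interval forward rates
all exceed 0.35 of the burst elevation (minus one expected burst interval,
removing the first-spike wait bias).  Two details matter for validity and
were chosen deliberately: the search window is fixed relative to the go
cue, and the refinement threshold uses the stratum-averaged (not the
trial's own) movement-epoch rate — tying either to the trial's own movement
would leak movement timing into the detected onset and fabricate jitter
correlations.

**Movement-epoch (ME) rates** are counts over [−60, +20] ms around hand
onset and [−30, +30] ms around saccade onset, minus the count-based
baseline rate.  **Half-widths** use the threshold halfway between baseline
and peak.  For per-target durations the half-width is read off the
median-over-trials aligned rate, smoothed with a 51-ms boxcar: per-trial
R_n peaks are inflated by short-interval fluctuations and fragment the
half-height region (a symmetric kernel leaves the half-height width of a
burst unchanged).  Targets without a significant ME discharge are
discarded; implausibly long widths (>3 MADs above the condition median)
are trimmed as noisy measurements.

## Directional tuning

Tuning is fit by nonlinear least squares to A·e^{k cos(θ−μ)}/(2π I₀(k)),
initialized from the rate-weighted circular mean and the resultant-length
inversion of k, with 8 restarts over μ offsets; a brute-force grid search
(closed-form A per (μ, k)) serves as an independent oracle.  The field
width is 2/√k converted to degrees.  Two analytic anchors: the half-width
at half height of 1 + cos θ is exactly 90°, and the least-squares von Mises
width of the same field sampled at the 8 task directions is 116.5° (≈117;
dense sampling gives the same value, so the 8-point/continuous question is
immaterial).  2-D movement fields are Gaussian(amplitude) × von
Mises(direction) least-squares surfaces; with one amplitude the Gaussian is
unidentifiable and a flagged direction-only fit is returned.  Dynamic
fields tile −30…+120 ms around saccade onset with half-open 20-ms windows
(the last window ends at +130 rather than truncating).

Circular statistics: the Rayleigh test is delegated to pingouin; the
Watson–Williams two-sample test is implemented with the 1 + 3/(8κ̂)
correction and flags low-concentration inputs, with an exact permutation
variant alongside.

## Timing analysis

Jitter regressions are OLS of one event's onset on the discharge onset
after aligning trials (within ±45° of the on-direction, inclusive) on the
other effector's onset — or on the go cue for the single-effector
follow-ups that guard against range restriction.  Cells need ≥8 usable
trials; detected onsets more than 3.5 scaled MADs from the median, and one
round of residual outliers, are dropped before the fit (single-trial onset
detection has a small heavy tail that would otherwise dominate the least
squares).  Latency spreads SD_E/SD_H compare per-trial effector latencies
after aligning on discharge onset, with Bartlett's test and a
Kepner–Randles-type nonparametric scale test.  The latter is implemented
from first principles (the source gives no formulas): under bivariate
symmetry the marginals have equal scales exactly when X+Y and X−Y (after
centering) are unassociated, so the statistic is Kendall's τ between sum
and difference with its large-sample normal null — mean-free, and
antisymmetric under coordinate swap.  It is validated purely by simulation
(type-I error, power at scale ratio 3, invariances).

## Classification

The screening gate admits a cell as Meq when its ME rate significantly
exceeds background (unpaired t-test, α = 0.05) in the eye, hand *and*
eye-hand conditions and its median discharge onset precedes movement onset
for both effectors; otherwise it is binned as visual-only (target-locked
response only), post-movement-only, phasic-premovement, or non-task.

*On-direction*: equality of eye and hand preferred directions is decided by
an exact permutation test whose statistic is the distance between the
rate-weighted mean direction *vectors* of the two conditions.  This
replaces a parametric circular-means test deliberately: with ~160° fields,
per-trial angular samples have resultant lengths far below the validity
range of the F-approximation, while the vector statistic keeps exact level
and near-unit power at the >90° separations that characterize non-invariant
cells.  Non-invariant cells are checked for dynamic drift first (slice pds
moving from the eye pd to the hand pd), then the eye-hand pd is matched to
the nearer single-effector pd within a radius of a quarter of the eye–hand
separation (capped at 45°); matching neither is "intermediate".

*Intensity* and *Duration* use three-way unpaired t-tests (eye vs hand,
then eye-hand vs each) with a 25% relative-mean equivalence guard — without
it, large trial counts convert small measurement biases into preference
labels.  Direction-dependent eye-hand durations (short near the eye pd,
long near the hand pd, ratio < 0.6 and significant) are "mixed".

*Onset*: significant hand coupling comes from saccade-aligned trials
(predicting hand onset), significant eye coupling from hand-aligned trials;
a cell significant for only one effector is promoted to "both" if the other
effector's go-aligned single-effector regression is significant, and a cell
with neither coupling but both follow-ups significant is also "both".

On the calibrated 55-cell population (10 trials per condition × direction ×
amplitude) every column recovers ≥ 93% of generator labels.

## Decoding

The decoder is a 55-input, 50-hidden, 8- or 3-output tanh network trained
on sum-of-squared error against one-hot targets, argmax readout, 60/5/35
stratified split, inputs z-scored on the training split.  Weights start
uniform, scaled by 1/√fan-in — the unscaled ±1 range saturates every tanh
unit over 55 standardized inputs and training never leaves chance.
Training is full-batch Adam (an adaptive batch method; the procedure is
accuracy-based, not trajectory-based) with per-epoch validation checks; the
parameters at the best validation error are kept, and the best of 10
restarts by validation error is evaluated on the held-out test set.

Inputs are per-trial *steady-state discharge intensities*: for each (cell,
condition, direction) stratum the half-width window of the median-aligned
rate is found once, and each trial contributes its baseline-subtracted
count rate in that window.  This mirrors the burst-intensity measure that
spans 18–166 spikes/s; the brief ME windows are available as an option but
their counting noise caps even ideal direction decoding near 90%.  Each
sample draws every cell's value independently from that cell's trials of
the stratum (40 samples per stratum by default).  Ablation curves remove n
random cells of one class (invariant vs non-invariant preferred direction),
retrain (single restart per repetition), and average over 200 repetitions;
per-size unpaired t-tests compare equal-size populations of different
composition.  On the calibrated population, direction accuracy is 94–96%
and effector accuracy ~99%; removing invariant cells degrades direction
decoding while removing non-invariant cells degrades effector decoding,
with no detectable difference when only 7 cells are removed.

## What the synthetic data do and do not show

The generator reproduces the *reported statistics* of the recordings — the
task structure, duration laws, lead times, rate ranges, field widths,
category composition and timing-lock taxonomy — with Poisson spiking and
rectangular burst envelopes.  Passing tests therefore demonstrate that the
estimators and decision procedures recover known ground truth under
realistic noise, and that the analytic anchors (90°, ≈117°, ρ² ≈ 0.49)
are computed correctly.  They do not establish anything about real tissue:
real bursts are not rectangular, real spike counts are often non-Poisson,
real preferred directions drift with amplitude and speed, and the decoder
results are a scaled-down surrogate for the unavailable 55 recorded cells.
Quantities tied to the recordings themselves (counts of recorded/excluded
neurons, the R_E = 18 + 0.73·R_H regression, anatomical locations) are
used only as generator calibration, never as validation targets.

## Problem sizes and numerical choices

Default test/benchmark sizes: 10 trials per condition × direction ×
amplitude (480 trials per session), 55-cell populations, 40 decoder samples
per stratum, 200 ablation repetitions at removal sizes {7, 22}, 1000–2000
simulations for type-I-error checks.  All randomness flows from explicit
seeds through per-trial substreams; re-running any stage with the same
inputs is bit-reproducible.  Times are ms from trial start; angles degrees
in [0, 360), 0° right, counter-clockwise positive, throughout.
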