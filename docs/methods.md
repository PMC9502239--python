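# Methods

`walkpd` detects Parkinson's disease (PD) from multi-day, free-living,
wrist-worn inertial recordings: triaxial accelerometer (unit g) and triaxial
gyroscope (unit deg/s), nominally 100 Hz. The pipeline has four stages —
preprocessing, dynamic-activity gating, walk-like event detection, and
event-level PD classification aggregated into daily diagnoses — evaluated
under leave-one-subject-out cross-validation with a temporal holdout.

## Preprocessing

Recordings are low-pass filtered and decimated from 100 Hz to a 20 Hz
analysis rate. Human activity and tremor content of interest lies below
10 Hz, so 20 Hz sampling preserves it while shrinking the data fivefold. The
anti-alias filter is a zero-phase FIR (Hamming design, cutoff at 0.45 x
target rate, applied forward-backward), attenuating content above the target
Nyquist far beyond 40 dB. The stream is cut into non-overlapping 5-s windows
(L = 100 samples at 20 Hz). Windows never span a calendar-day boundary (day
= calendar day at a fixed UTC offset, default +00:00), so daily votes are
well defined; trailing partial windows are dropped rather than padded.
Timestamp gaps longer than 1 s (non-wear, charging) split a recording;
shorter irregularities are tolerated.

## Dynamic-activity gate

Amplitudes are compared per subject against an adaptive threshold computed
from the subject's first recorded day only: over that day's 5-s windows,
half the maximum of the dominant-axis detrended mean absolute value (MAV).
Detrending (per-window mean subtraction) is load-bearing: without it a
resting wrist carries ~1 g of gravity on the accelerometer and the half-max
rule would gate on orientation, not movement. The dominant axis — the axis
with the highest detrended MAV, ties toward x < y < z — makes the rule
insensitive to watch placement. A window is *dynamic* when its dominant-axis
accelerometer MAV strictly exceeds the subject's accelerometer threshold.
The gyroscope threshold is computed and stored for audit but does not gate.

## Walk-like detection

For each dynamic window, the power spectral density of the dominant
gyroscope axis is estimated by Welch's method: 2-s Hann-tapered segments,
50% overlap, mean-detrended, one-sided density normalization. 2-s segments
give 0.5 Hz resolution, enough to separate the 0.6-2 Hz walking band from
its complement. The window is *walk-like* when

* the mean PSD over bins inside 0.6-2 Hz strictly exceeds the mean PSD over
  the remaining non-DC bins (means, not sums, so unequal bin counts do not
  bias the comparison), and
* the band mean is at least the absolute power floor of 100 (deg/s)^2/Hz,
  which suppresses low-energy oscillations (fidgeting, vehicle vibration).

Only walk-like windows proceed to classification.

## Event classifier

A 1D convolutional network maps one 6 x 100 walk-like window to P(PD):
four convolutional blocks (kernel 5, stride 2, "same" padding, no pooling;
channels 8, 16, 32, 64), each block conv → batch normalization → ReLU with
an L2 penalty (1e-4) on the kernels; 50% dropout after the last block; the
7 x 64 = 448-unit flattened output feeds a 2-unit softmax head. Temporal
length halves per layer (100 → 50 → 25 → 13 → 7) while the receptive field
of a final-layer step grows to 61 input samples (~3 s of movement).
Training: Adam (lr 1e-3), batch size 64, cross-entropy on one-hot targets
(the two-class softmax form of binary cross-entropy), at most 50 epochs.
The implementation is pure NumPy (im2col convolutions with exact analytic
gradients, verified against numerical differentiation in the test suite),
so training is bit-reproducible from the seed and inference is a pure
function of the inputs.

### Input canonicalization

Each window is mapped to a canonical axis frame before standardization: the
per-channel window mean is removed (gravity projection and gyro bias are
orientation fingerprints, not movement), the three axes of each sensor are
sorted by detrended MAV with the dominant axis first, and each axis' sign is
fixed so its third central moment is non-negative. Channels are then
z-scored with statistics pooled per sensor over the training windows only.

This choice is load-bearing. Watch orientation is fixed per subject but
arbitrary across subjects; with raw channel order, per-channel statistics
encode subject identity, batch-norm inference statistics misnormalize unseen
subjects, and leave-one-subject-out accuracy collapses below chance. Two
alternatives were evaluated and rejected: per-channel z-scoring alone (the
failure just described) and train-time random axis permutation augmentation
(the invariance task overwhelms a 15k-parameter network; held-out accuracy
plateaued near 0.6). Canonicalization reuses the same dominant-axis idea
that makes the rules-based detector orientation-invariant.

### Early stopping and model selection

Model selection never touches the held-out test subject. Within each fold,
one HC and one PD subject are set aside from the training set (deterministic
choice: last of each class in sorted order) as an inner validation set. A
*selector* trains on the remaining subjects for the full epoch budget (50)
and the epoch with the best inner-validation loss is selected (improvements
smaller than 0.02 in loss are ignored); optional early stopping — a patience
below the epoch budget, never firing before epoch 30, since
subject-invariant features emerge late on cohorts this small — can shorten
the search. The untrained initial state is a selection candidate
whose validation loss is the baseline: if no epoch beats it, the fold model
abstains (near-uniform outputs) rather than return a memorized fit. This
matters for calibration: when the two groups are statistically exchangeable,
a small cohort still lets the network memorize training subjects, and
monitoring anything the optimizer has seen would hand back a confidently
wrong subject-fingerprint model. When an epoch does win, the fold model is
*refit* on all training subjects (inner-validation pair included) for
exactly the selected number of epochs — with only a handful of subjects per
class, excluding two from the gradient set costs more signal than the epoch
choice is worth. When a class has fewer than two training subjects no inner
split is possible and the trainer monitors training loss.

## Evaluation protocol

Leave-one-group-out (LOGO) with subject as group: each subject is the test
subject in exactly one fold; a leakage guard asserts that no test-subject
window enters training or inner validation. Training and validation use each
subject's first 10 *recorded* days (days with any data). Temporal stability
is tested on three holdout blocks — the first 5 recorded days at least 30,
60, and 90 days after the subject's first recording day — predicted with the
fold's frozen model; blocks overlapping the training interval are rejected,
and missing blocks are reported absent, never imputed.

The daily diagnosis is the majority vote over a day's event predictions
(event is PD when P(PD) >= 0.5); a tied day votes PD, favouring sensitivity.
Days with no walk-like events yield no decision and are excluded from daily
accuracy. Per-class accuracies are averaged per subject first, then across
the subjects of each class, so subjects with more walking do not dominate.

Walking duration is summarized as daily walk-like hours (window count x 5 s
/ 3600) per subject-day, compared between groups with Welch's
unequal-variance t-test.

## Comparison classifiers

Four classical methods consume a 35-element feature vector per window: per
sensor and axis the mean, variance, skew, and Fisher excess kurtosis (24),
the maximum absolute amplitude per sensor (2), and accelerometer band powers
per axis for 0-4 Hz (DC excluded), 4-9 Hz (the tremor range), and 9
Hz-Nyquist (9). Band powers mean-detrend, Hann-taper, FFT, and sum |X(f)|^2
over half-open bands, the last closed at Nyquist, so the three bands
partition total non-DC power exactly. Zero-variance axes return skew =
kurtosis = 0. The methods are scikit-learn estimators with default
hyperparameters: logistic regression, random forest, gradient-boosted trees,
and elastic net realised as elastic-net-penalized logistic classification
(l1_ratio 0.5, saga solver) since the outcome is binary; linear methods
standardize features with training statistics. All four run on exactly the
same LOGO folds as the network.

## Synthetic cohorts

Real multi-day wrist recordings from PD cohorts are access-restricted, so a
generator produces labelled stand-ins. Per subject-day: a constant 1 g
gravity vector on a random, slowly wandering orientation plus white sensor
noise (rest); 2.5-8 Hz band-limited bursts (non-walk dynamics, accelerometer
amplitude 0.25 g — comparable to but below walking so the day-1 half-max
threshold keeps gating on walking, which is the adaptive rule's working
assumption); and walk bouts placed by a renewal process (exponential gaps)
so the configured bout rate and occupied fraction are realised exactly.
Walking is a quasi-periodic oscillation — fundamental per subject from
0.8-1.8 Hz plus a 0.4-amplitude harmonic, phase advanced cycle by cycle —
on a subject-fixed dominant axis (dominant weight 0.85-0.98), with matched
accelerometer modulation (150 deg/s and 0.35 g scales). Bout-to-bout
variability (cadence jitter, lognormal amplitude factor, direction wobble,
15% broadband gait noise) keeps subject identity from being a trivially
learnable fingerprint, as in real behaviour where no two walks are alike.

PD effects, all tunable and nullable: walking amplitudes scaled by 0.65
(bradykinetic attenuation), an added tremor tone at a subject-specific
4-6 Hz frequency (60 deg/s, 0.12 g — a moderate rest tremor), cycle-time
jitter raised from 0.03 to 0.15 relative SD, and a lower bout rate (12.6 vs
16.6 bouts/h; with ~68 s mean bouts and 18 h wear this yields ~4.3 vs
~5.65 daily walking hours). Defaults were chosen so that, at these effect
sizes, single-event separability sits near the 90% regime and the walk
detector operates above 0.95 sensitivity/specificity — the conditions the
pipeline is designed for. Between-subject nuisance variation (cadence,
orientation, amplitude habits) is deliberately large, and within-subject
bout-to-bout variation larger still, so the class signal — not subject
identity — is the most stable thing a model can learn.

What the generator does **not** emulate: biomechanically realistic gait
(no stride asymmetry, turning, or surface effects), diurnal or medication
cycles, sensor drift and temperature effects, postural transitions, or
non-walk activities with walking-band periodicity (cycling). Passing tests
therefore demonstrate that the pipeline recovers the programmed class
structure under free-living-like interleaving and orientation nuisances —
not clinical performance on real cohorts.

## Problem sizes and numerical choices

Evaluation cohorts simulate 8 subjects (4 HC, 4 PD) at 0.4 wear-hours per
day — the package's chosen desk-scale condition, enough for ~60-130 walk
events per subject-day so daily votes rest on meaningful samples — over the
first 10 days plus 5-day blocks a month, two months, and three months out;
this yields roughly 14,000 walk-like windows and trains 8 networks in
minutes.
The full-wear default (18 h) is retained in `SimulationConfig` for
realistic duration studies. Ties in dominant-axis selection break toward
x < y < z; the dynamic gate and band dominance use strict inequalities, the
power floor uses >=; a vote fraction of exactly 0.5 decides PD. Degenerate
inputs (empty days, constant windows, missing holdout blocks) return
defined values or explicit absences rather than NaN.

## Known limitations

* The power floor (100 (deg/s)^2/Hz) is inherited as a convention and
  interacts with gyroscope units; other devices may need recalibration.
* With very small cohorts a single atypical subject (for example the
  slowest walker, whose cadence has no same-class neighbour) can remain
  hard to classify; the daily majority vote absorbs this as long as the
  per-day event accuracy stays above one half.
* The elastic-net and logistic baselines assume standardized features; tree
  ensembles consume raw features. None are tuned. The 35 features are
  computed on raw axes (no orientation canonicalization — their definitions
  are per-axis), so on synthetic cohorts with subject-fixed watch
  orientations the baselines are orientation-confounded and their
  leave-one-subject-out accuracy varies strongly with the cohort draw; the
  network, which classifies canonicalized windows, does not share this
  failure mode.
* Day boundaries use a fixed UTC offset; no timezone inference is attempted.
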