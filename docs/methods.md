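# Methods

## Problem and prediction unit

In a repeated public goods game (voluntary contribution mechanism), groups of
four communicate face to face for three minutes before play. The package
predicts a binary end-game outcome — whether the group contributes fully in
the very last period — from the nonverbal signal of that conversation alone.
The prediction unit is the group, not the individual: end-game behaviour of
each member is assumed to be shaped by the whole group's interaction, so the
four members' signals enter one descriptor and one label.

Input is not video but the tabular output of an upstream facial-feature
extractor (OpenFace-style CSV): per frame, a tracking confidence/success
flag, three head rotations (pitch, yaw, roll, radians) and facial action
units (AUs) as 17 intensity channels in [0, 5] and 18 presence channels in
{0, 1} — 38 channels in total. Four named channel subsets are used: FF1 (all
38), FF2 (pose + presence, 21), FF3 (pose + intensity, 20) and FF4 (pose +
8 robustly estimated intensity AUs + 10 robustly estimated presence AUs, 21).

Frames that fail the quality gate (success = 0 or confidence below a
configurable floor, default 0.5) are repaired by linear interpolation between
the nearest valid neighbours; edge runs copy the nearest valid frame, and
presence channels are re-binarised at 0.5 afterwards. Descriptor statistics
need gap-free signals, and interpolation preserves the series length so
temporal-split boundaries stay comparable across participants.

## Facial activity descriptors (FADs)

Each channel of one participant over one contiguous temporal segment is

1. smoothed with a first-order Butterworth low-pass at 1 Hz, applied
   forward–backward (zero phase) so time-of-extremum statistics are not
   phase-shifted;
2. differentiated twice by backward differences scaled by the frame rate,
   with the first edge value replicated (`d1[0] = d1[1]`) to keep the length
   constant without creating a spurious extremum at t = 0;
3. summarised by 16 statistics on each of the three signals (smoothed, d1,
   d2).

The 16 statistics, in frozen layout order: mean; population standard
deviation; minimum; maximum; range; median; interquartile range; RMS;
relative time of the maximum (argmax/(N−1), 0 for N = 1); relative time of
the minimum; fraction of samples strictly above the mean; relative count of
mean crossings; mean absolute deviation from the median; least-squares slope
versus relative time in [0, 1]; first quartile; third quartile. "Strictly
above the mean" makes a constant signal score 0 rather than 1. A FAD is
therefore `channels x 3 x 16` long: 1824 (FF1), 1008 (FF2/FF4), 960 (FF3).

Statistics are computed on unnormalised channel values: the downstream tree
ensemble is invariant to monotone per-feature scaling, and normalisation
would distort the physical units of pose and AU channels.

Temporal segments come from k-way equal splits (k in {1, 3, 4, 5}); segment
boundaries are `round(i * n/k)` with round-half-up, so lengths differ by at
most one frame. Multi-part split models compute one FAD per contiguous part
and concatenate the parts in temporal order — segments stay temporally
coherent rather than being pooled into one discontiguous signal.

## Group activity descriptors (GADs)

The four participant FADs are concatenated in all 4! = 24 slot orderings
(enumerated lexicographically), each ordering yielding one training instance
with the group's label. This augmentation encodes that participant order is
meaningless while multiplying the effective sample size, at the price of 24x
correlated instances per group. Instance layout is participant-major,
segment-minor. Whole-video GAD lengths: FF1 7296, FF2 4032, FF3 3840,
FF4 4032; a 127-group study yields 3048 instances.

## Classification and evaluation

The instance classifier is a random forest (sqrt(d) features per split,
unlimited depth, bootstrap); the per-instance vote is the majority of the
trees' hard predictions (a probability-averaging mode exists behind a flag
for sensitivity analysis). A group's score is the mean of its 24 instance
votes, and the group prediction is `score >= theta`. Baselines: a trivial
classifier that always predicts the training majority class (tie predicts 1)
and an optional linear-kernel SVM fitted on training-fold-standardised
features.

Evaluation is leave-one-session-out (LOSO): subjects can recur across groups
only within a session, so holding out whole sessions guarantees
subject-independent folds (an explicit leakage audit is provided). Fold
accuracies are averaged unweighted across sessions; a group-weighted mode
exists behind a flag because sessions contain unequal group counts.

The threshold theta is either fixed at 0.5 or tuned by nested CV: per outer
fold, an inner LOSO over the outer-training sessions produces group scores,
the grid of all 25 achievable vote fractions k/24 is evaluated exhaustively,
and the grid member with the best mean inner accuracy wins. Ties (common,
because accuracies of adjacent thresholds are often exactly equal) are broken
by proximity to 0.5, then by the smaller value; mean accuracies within 1e-12
are treated as tied because genuinely equal rational accuracies can differ in
the last float bit. Per-fold forest seeds are derived from a keyed blake2s
hash of (held-out session id, experiment seed), so folds are reproducible and
independent of evaluation order.

Temporal-split experiments use a frozen 33-entry catalogue of models in three
categories (combined / beginning / end, 11 each, including the middle-fifth
entry that appears in both beginning and end) plus the 12 single-part base
splits. Category summaries report mean/min/quartiles/max both over model
means and pooling fold accuracies. The five-step ablation runs: whole video
with a small forest; a large forest; plus tuned threshold; the combined-split
category; the end-split category.

Model comparisons use a two-sided paired Wilcoxon signed-rank test on
per-fold accuracies, with zero differences dropped ("paired U-test" is
contradictory terminology; the paired reading is the default and an unpaired
Mann–Whitney U mode is exposed). Comparisons against the uninformed guess use
the constant vector 0.5. Identical fold vectors return p = 1 by convention.

## Synthetic data

Real recordings are not distributable, so the generator emulates the
*extractor output*, not video. Per channel it draws stationary first-order
autoregressive processes — the simplest model with tunable smoothness:

- pose: mean 0 rad, sd 0.15 rad, lag-1 autocorrelation 0.99 (slow head
  motion at 25 fps);
- AU latent: mean 0.5, sd 0.5, autocorrelation 0.97; intensity is the latent
  clipped to [0, 5]; presence is the indicator that the latent exceeds the
  70th percentile of its stationary distribution, giving sparse on/off
  activations (AU28, presence-only, has its own latent).

Defaults mirror the study conditions: 24 sessions, 3-minute videos at 25 fps,
four members per group, per-session participant pools with within-session
reuse only, Bernoulli(0.5) labels. A label effect is a mean shift of
`effect_size` channel standard deviations applied to selected pose/intensity
channels inside a chosen time window (default: the last third), identically
for all four members of label-1 groups — embodying the hypothesis that
less-committed groups behave differently late in the conversation. Presence
channels inherit the effect through their latent.

What the generator does not emulate: cross-channel correlation structure of
real faces, turn-taking and conversational dynamics, heavy-tailed AU burst
statistics, tracking-failure patterns, and any person-specific idiosyncrasy
beyond process noise. Passing tests therefore demonstrate that the machinery
is correct and can recover a time-localised group effect of realistic
magnitude — not that real conversations are predictable at any particular
accuracy.

## Validation study conditions and problem sizes

- Null calibration: effect size 0, balanced labels, 120 groups in 4 sessions
  of 30, FF4, 100 trees, 60 s videos, 10 replicates; the mean LOSO accuracy
  must fall in the 120-group binomial chance band [0.42, 0.58] in at least
  9 of 10 replicates. (Four large sessions rather than many small ones keep
  the group total — which sets the band width — while bounding the number of
  forest fits.)
- Planted-effect recovery: effect size 1.5 on pose yaw + AU07/AU17/AU45
  intensities in the last third; nested CV on 6 sessions of 5 groups, 50
  trees, 10 replicates, requiring mean accuracy >= 0.80 in at least 8;
  additionally, over 3 replicates of the full 33-model catalogue (5 sessions
  of 5 groups, 30 trees), end-category models must outperform
  beginning-category models on average.
- Descriptor correctness: equality with an independent brute-force
  re-implementation (hand-derived bilinear filter coefficients, naive-loop
  statistics) to 1e-9 relative tolerance on 100 random fixtures.

Numerical notes: the digital Butterworth filter's response follows the
bilinear frequency mapping, so attenuation at frequencies well above the
cutoff is somewhat stronger than the analog formula suggests (at 5 Hz with
25 fps: |H|^2 ≈ 0.029 versus 1/26 analog); near the cutoff and below, the two
agree. Quartiles use linear interpolation between closest ranks. Mean
crossings count strict sign changes of the centred signal. Instance matrices
are stored as float32 (the forest's internal dtype); descriptor computations
are float64.

## Known limitations

- The 16-statistic list beyond the five canonical ones (mean, max, sd, time
  of max, duration above mean) is this package's frozen choice of standard
  descriptor statistics; other implementations of the same idea may differ.
- Absolute accuracies on real data are out of reach by construction; all
  statistical claims are about synthetic data.
- The SVM baseline is a single fixed configuration (linear, C = 1) intended
  as a reference point, not a tuned competitor.
- Nested CV retrains one forest per inner fold; with S sessions a full run
  costs S(S−1)+S fits, which dominates runtime for large S.
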