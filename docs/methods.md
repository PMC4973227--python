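# Methods

This note records the models, parameter choices and numerical decisions
behind `lamflow`, and what the synthetic tests do and do not establish
about real recordings.

## Epoch frame

Recordings are resampled from 1000 Hz to 400 Hz with polyphase anti-aliased
resampling (`scipy.signal.resample_poly`, ratio 2/5) and receive no other
filtering or preprocessing: the analysis targets nonlinear structure that
filtering could distort. Epochs are 12 s (4800 samples) on a 5-minute
grid anchored at t = 0 of each recording; sampling stops at 144 h, or one
hour before the first seizure when a seizure time is supplied. Windows
that would overrun the recording are skipped, never padded, so epoch
length is exact by construction. 24-hour bin edges are [0, 24), [24, 48),
…, tiling [0, 144].

## Embedding

- Dimension `m = 12` (fixed; no false-nearest-neighbour estimation).
- Delay `τ`: first local minimum of the time-delayed mutual information,
  computed per epoch. The MI estimator uses equal-occupancy (quantile)
  bins, 16 by default, over lags 1–100 (0.25 s at 400 Hz). Equiprobable
  binning is invariant under monotone amplitude transforms and robust to
  the outliers of raw unfiltered signals. The local-minimum rule is
  strict on the left and non-strict on the right, so the first entry of a
  flat valley wins. When no interior minimum exists within the lag range
  the delay falls back to the first lag where MI drops below MI(1)/e, and
  to τ = 1 as a last resort; both fallbacks warn but keep batch runs
  total. Bin count and lag range are package defaults, chosen once.
- Theiler window `w = (m − 1)·τ`, applied to pair counting *and* line
  accounting: recurrence entries with |i − j| ≤ w are blanked before runs
  are scanned, so vertical/diagonal runs truncate at the band boundary.
  The alternative (masking counts but letting runs bridge the band) is a
  known ambiguity of recurrence software; truncation was chosen because
  the window exists precisely to remove tangential-motion artifacts, and
  letting runs cross it would re-admit them. The choice is localized in
  `structure_from_matrix` / `recurrence_structure`.

## Recurrence analysis

Distances are Euclidean in the embedding space, computed once per epoch
and normalized by the maximum pairwise distance, so the radius RAD is a
percentage and every statistic is scale-invariant. One global radius is
solved per epoch (the fixed-REC procedure defines a single scalar) by
bisection on the normalized radius with the achieved REC evaluated by
binary search over the sorted valid distances; 60 iterations, bracket
tolerance 1e-4. The upper bracket end is returned, guaranteeing
REC ≥ target; tied distances can make REC jump past the target, in which
case the overshoot is accepted and flagged when it exceeds 0.05
percentage points. The recurrence-rate target is 1 %, inside the
power-law tract of the REC-vs-RAD scaling curve (see below).

Line statistics use minimum vertical length 2 and minimum diagonal
length 5 (noise inflates short diagonals). Vertical lines are counted on
all columns of the symmetric matrix; diagonals on the upper triangle
beyond the Theiler band (by symmetry the DET fraction equals the
full-matrix value). LAM is normalized by the solved radius (LAM/RAD)
because under fixed REC the raw LAM no longer tracks laminarity: an epoch
reaching 1 % recurrence only at a large radius has weak recurrence
structure, and dividing by RAD restores the ordering. Degenerate epochs
(constant signal, coincident vectors) yield flagged null rows, not
exceptions.

The preliminary scaling analysis solves RAD for REC targets
{0.1, 0.5, 1, 2, 5, 10} % and summarizes log10(REC) vs log10(RAD) over the
0.05–2 % tract by least squares (slope ≈ effective correlation dimension,
R² as a straightness QC). Visual inspection of the log-log plot is
replaced by these two numbers so batch QC is automatable.

## Nonlinear cross-prediction (NCPE)

The zeroth-order predictor embeds train and target series with the
epoch's (m, τ), finds for each target state its k = 5 nearest train
states (fixed neighbour mass rather than a fixed radius: every state gets
a prediction and the operation is deterministic), and predicts the h-step
future as the mean of the neighbours' h-step futures, h = 1…50. Errors
are per-step RMS over target states, divided by the SD of the predicted
dataset; target states whose h-step future falls off the end are dropped
from that step, and neighbour candidates are restricted to train states
with a full 50-step future. Theiler-style exclusion of temporally
overlapping train states is supported for self-prediction setups.

Both curves train on the **first half** of the epoch: NCPE-det predicts
the second half forward, NCPE-trev predicts the time-reversed second
half. Training set and predicted data are therefore identical between
the two cases up to the direction of time, which makes the comparison
exchangeable under time reversibility: on linear Gaussian AR epochs the
max-NCPE distributions are then statistically indistinguishable, as they
must be. Training the trev case on the whole epoch instead (a natural
reading of the original description) gives it a neighbour pool and an
error-curve noise level different from det's, and that structural
asymmetry alone separates the two maxima on time-reversible null data —
the design used here removes that artifact. Per epoch the maxima of the
two curves are retained; groups are compared per 24 h bin with
Mann-Whitney (det vs trev) and Kruskal-Wallis/Dunn across groups.

Phase-randomized surrogate testing is deliberately absent: on signals
with strong periodic components it produces both false positives
(spectrum mismatch) and false negatives (randomized surrogates of a
periodic signal are still periodic). The Welch-based periodicity screen
(peak > 10× the local spectral median, 31-bin running median, DC
excluded) documents per epoch that this condition is common, which is why
the cross-prediction route is used.

## Group statistics and ROC

Within each 24 h bin, group values are compared with Kruskal-Wallis;
Dunn's rank-based pairwise test (standard z statistic with tie
correction) follows only when KW p < 0.05, Bonferroni-adjusted over the
three pairwise comparisons. A D'Agostino-Pearson normality p-value is
recorded per cell for the report but never switches the test family — the
analysis is nonparametric throughout. The ROC uses one observation per
subject (median score over t ≥ 72 h) to avoid pseudo-replication, with a
pooled per-epoch variant behind a flag; AUC is computed by the
Mann-Whitney rank construction, so it comes with the corresponding
two-sided p-value.

## Synthetic data: what it emulates and what it does not

The generator stands in for undeposited multi-day single-channel
recordings. Its components:

- **Intermittent map** `x → (x + c·x^z) mod 1`, a Pomeau–Manneville-type
  map with a marginally stable fixed point at 0: long near-constant
  laminar stretches interrupted by reinjection bursts (type-I
  intermittency). Defaults c = 0.2, z = 2.0 put laminar durations in the
  10²–10³-sample range so a 12 s epoch contains several laminar phases
  *and* bursts — the alternation regime the method targets. Much smaller
  c stretches a single laminar phase over the whole epoch (epochs become
  numerically flat); much larger c leaves bursts only. Burn-in 1000
  iterates.
- **AR null**: stationary zero-mean Gaussian AR(p) via `lfilter`, with a
  stationarity check on the characteristic roots; AR(1) with coefficient
  0.9 is the default null.
- **Periodic + noise**: sinusoids below Nyquist plus Gaussian noise, for
  exercising the periodicity screen.
- **Mixture epochs**: both components generated over the full epoch,
  standardized to unit SD (λ steers dynamics, not variance), then exposed
  in alternating 0.5 s blocks, each block Bernoulli(λ) intermittent vs
  AR. Block-wise mixing preserves laminar phases that pointwise averaging
  would destroy.
- **Cohorts**: three groups with piecewise-linear λ(t) profiles over
  0–144 h (persistently 0.8; 0.8 declining to 0.1 by 72 h; persistently
  0.1). Subject/epoch random streams derive from
  `SeedSequence(design_seed, spawn_key=(group, subject, epoch))`, so
  cohorts regenerate bit-identically. Because a 144 h recording at
  1000 Hz (~5·10⁸ samples per subject) cannot reasonably be materialized,
  cohort subjects are synthesized directly on the epoch sampling grid
  (each grid point one continuous 1000 Hz segment with weight λ(t));
  continuous recordings for exercising the resampling/epoching path are
  available separately via `generate_recording`.

The generator makes no claim of physiological realism: no ECoG spectral
content, seizure morphology, artifacts, nonstationary noise floors or
amplitude units. Passing tests therefore establish that the pipeline
detects and tracks controlled intermittency through resampling, embedding
and statistics — not that it would achieve any particular sensitivity on
real ECoG.

## Problem sizes in the shipped checks

The end-to-end checks run at desk scale, chosen as the package's own
test-design sizes: 50 epochs per condition for the discrimination and
time-asymmetry comparisons (4800-sample epochs; map fixtures are map
iterates at the analysis length, while cohort epochs go through the full
1000 → 400 Hz path); a 3 × 3-subject cohort sampled every 6 h over 144 h
(12 epoch values per group-bin) for the group-recovery check; N ≤ 200
states for exact brute-force oracle equality; 2000 points for the planar
dimension-recovery check. Fixed seeds make every check reproducible.

## Known limitations

- Single-channel analysis only; no montage handling, no seizure
  detection (first-seizure times are inputs), no EDF reader (plain
  CSV/TSV only).
- RQA measures beyond REC/LAM/VMAX/TT/DET (entropy, divergence, trend)
  and windowed/cross/joint recurrence variants are out of scope.
- The MI bin count, lag range, NCPE neighbour count and periodicity-screen
  factor are defensible defaults, not estimated quantities; all are
  exposed as parameters.
- Whether line runs should truncate at the Theiler band is genuinely
  ambiguous (see above); the implementation commits to truncation and
  keeps the decision in one place.
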