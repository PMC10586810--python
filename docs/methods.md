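# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the open design decisions behind `mvpalink`, in the
spirit of the methods documentation of mature analysis packages.

## The analysis chain

All empirical stages operate on an `EpochSet`: a
`(trial, channel, time)` tensor with a row-aligned trial table
(participant, scene, binary category, task, correctness, reaction time).
Time is in milliseconds relative to stimulus onset at 0; bins are labelled
by their centers.

### Preprocessing

* **Baseline correction** subtracts, per trial and channel, the mean over
  a prestimulus window (default −200..0 msec). Idempotent by
  construction.
* **Downsampling** replaces non-overlapping groups of `factor` samples by
  their mean; a trailing remainder is dropped and new bins take the group
  center as their latency.
* **Multivariate noise normalization** multiplies every time-point
  pattern by Σ^(−1/2), with Σ the channel covariance pooled over all
  trials and the *entire* epoch, estimated per participant. The estimator
  is Ledoit–Wolf shrinkage (a convex combination of the empirical
  covariance with a scaled identity, data-driven weight) unless a fixed
  shrinkage weight is requested. The inverse square root is computed by
  eigendecomposition with an eigenvalue floor of 10⁻¹⁰ × the largest
  eigenvalue; an unregularized fit on rank-deficient data raises an error
  advising shrinkage. Caveat, stated openly: the whitener is fit once per
  participant on all data rather than inside cross-validation folds, so a
  small amount of information can in principle leak across folds; the
  null-calibration results below show this does not inflate the d2h false
  positive rate in this pipeline.
* **Correct-trial filtering** keeps rows flagged correct and warns when a
  scene loses all of its trials.

50-Hz low-pass filtering is an acquisition-side step and is *not*
re-implemented; the synthetic generator produces band-limited noise
instead (an upstream assumption, see below).

### Decoding

The classifier is a linear soft-margin SVM (libsvm through scikit-learn)
with fixed cost C = 1 and no per-feature rescaling beyond upstream
whitening. C is exposed only as a module constant because the analyses
are deliberately hyperparameter-free.

* **Scene identity**: per time bin and scene pair, pseudotrials of
  `group_size = 4` same-scene trials, leave-one-pseudotrial-out
  cross-validation; accuracy averaged over folds, pairs and repeats.
* **Scene category**: per repeat, each scene's (count-equalized) trials
  are split in half. Training halves are pooled *within category* and
  averaged into pseudotrials of `train_group_size = 20`; the test halves
  stay organized by scene and are averaged into **one pattern per
  scene**, so each scene yields exactly one signed decision value per
  time bin and repeat — the input the distance-to-hyperplane analysis
  requires. Trial-count equalization is applied globally per repeat (not
  per pair), and the random partitions are redrawn every repeat; repeats
  are aggregated by the arithmetic mean.

Sign convention: the positive decision side is the lexicographically
second category of the fitted boundary; a decision value of exactly zero
is classified as the first category (deterministic tie rule).

### Distance to hyperplane

The distance is the absolute value of the repeat-mean decision value —
regardless of classification correctness. Two sensitivity variants are
available behind flags: `order="mean_of_abs"` (average of |d| across
repeats; by Jensen's inequality it dominates the default) and
`signed_by_category` (decision values signed positive toward each scene's
own category). Per participant and time bin, Spearman's ρ (average ranks
for ties) is computed between the per-scene distances and the scene-level
**median RT over participants**; the participant's-own-RT variant is out
of scope. Cross-task pairings run the identical computation with the
recording and RT sources crossed and the pairing recorded in the output.
ρ is NaN where fewer than 3 scenes are available or either side is
constant; NaN cells are excluded from group means with a log entry.

### Channel searchlight

Channels live on 2-D layout coordinates (for synthetic data a
deterministic concentric-ring or single-ring layout). Each channel's
patch is itself plus its k = 4 Euclidean nearest neighbors (distance ties
break to the lower channel index); the decoding or d2h analysis runs on
the patch at a single latency — by default the peak of the corresponding
whole-pattern time course. At k = n−1 the searchlight reproduces the
whole-pattern analysis exactly (same RNG streams; asserted in tests). No
geodesic scalp distances: no electrode digitization is in scope.

### RSA and noise ceiling

EEG RDMs: per repeat, trial counts are equalized, pseudotrials of 5
trials per scene are formed, and the RDM entry for a scene pair is the
correlation distance (1 − Pearson r over channels) averaged over **all
cross-condition pseudotrial pairings** (the matched-pairing alternative
is a coin-flip the literature leaves open; all-pairs uses every sample).
Repeats are averaged as arithmetic means of distances, not of
correlations. Model RDMs standardize features across scenes (zero mean,
unit variance per feature; zero-variance features dropped with a log
entry) before the same distance. RDM pairs are compared by Spearman ρ of
their strict upper triangles; per model layer the time course is the
median over that layer's stages. The noise ceiling is the classical
leave-one-out lower bound and all-participant upper bound on the
attainable RDM correlation, with element-wise arithmetic mean RDMs.

A tie-structure subtlety worth knowing: Spearman ρ against a
tie-degenerate reference RDM (e.g. a purely categorical 0/2 matrix)
cannot reach 1 unless the data RDM carries the same ties, because tied
ranks shrink the rank variance. The planted-structure recovery test
therefore uses graded scene-unique patterns.

### Entropy-threshold readout

Entropy is Shannon entropy with 0·log 0 := 0, in **bits** (log2) by
default. The base matters — the fixed grid of 10 thresholds linearly
spaced on [0.01, 0.1] expresses a different confidence level in bits than
in nats — so the base is an explicit argument everywhere; natural-log
users pass `base=np.e`. "Reached" is inclusive (H ≤ threshold): the first
crossing of a confidence criterion. A scene that never reaches the
criterion in S stages gets RT S+1. Readouts taken after every
`stride`-th layer of a feedforward stack map onto stages 1..n//stride via
the adapter. Threshold selection is leave-one-participant-out: per fold
the threshold maximizing the Pearson r between network RTs and the median
RT of the remaining participants is selected (thresholds with constant
network RTs have undefined r and are excluded with a log entry), and the
held-out participant's own RTs score it; Pearson r is computed on the raw
integer RTs, ties and all. The final reported threshold is the modal
per-fold selection (ties to the smaller value).

### Group statistics

The sign-permutation test uses the statistic mean/SD (SD with ddof = 1)
across participants per time bin; one ±1 flip pattern per permutation is
shared across all time bins, preserving temporal dependence. Because
(s·x)² = x², the flipped SD is a function of the flipped mean alone and
the whole null is vectorized. P-values use the add-one convention
p = (1 + #{null ≥ obs}) / (1 + n_perm) so p is never zero; the exhaustive
mode enumerates all 2ⁿ patterns and reports the exact rank instead.
Zero-variance bins get p := 1 with a log entry. FDR control is the
standard Benjamini–Hochberg step-up with monotone adjusted p-values
capped at 1. The pipeline defaults follow common practice for these
analyses: right tail with α = .01 for decoding, left tail with α = .05
for d2h, right/two tails with α = .05 for RSA and model comparisons.

Peak-latency CIs are percentile bootstrap (no BCa — the simplest interval
consistent with how such CIs are usually reported), resampling
participants with replacement, n_boot = 1000, ties in the peak going to
the earliest bin; the difference-of-peaks CI uses paired resamples (the
same participant draw applied to both curves).

## The synthetic-data generator

The generator's purpose is to give every downstream stage an input with
the statistical structure it assumes, plus a ground truth to recover.

Latent model: each scene s has a signed margin m_s with
|m_s| ~ |N(separation/2, spread)| and the sign fixed by its category —
the folded-normal construction guarantees the sign never flips within a
category and degrades gracefully to m ≡ 0 at zero separation and spread.
A trial of scene s is

    x(c, t) = a(t) · m_s · w_c + noise(c, t)

with a(t) a raised-cosine ramp inside the effect window (0 at the edges,
1 at the center — smooth like an evoked response, no edge artifacts in
time-resolved decoding), w a unit-norm channel projection (seeded random,
or concentrated on requested channels for searchlight tests), and
Gaussian noise with a configurable channel covariance (identity /
diagonal / exponential-decay, validated PSD) and a unit-energy 3-bin
moving-average filter along time (band-limiting stand-in for the
acquisition low-pass; the filter is variance-normalized so the channel
covariance is exactly the configured one).

Reaction times implement the linking model the d2h statistic is designed
to detect: rt(p, s) = rt_base − λ·|m_s| + N(0, σ_rt), clipped at a fixed
floor of 150 msec (documented constant; keeps values physical after
noise). λ = 0 produces the matching null. Staged probabilities put
σ(gain·|m_s|·k·exp(ε)) on the true category at stage k with lognormal
jitter ε — monotone sharpening in expectation, exact (0.5, 0.5) forever
for a boundary scene.

Defaults are the standard validation design: 20 participants, 20 scenes,
16 channels, 120 five-msec bins spanning −200..400 msec, effect window
100–200 msec, separation 1.0, spread 0.25, unit noise, 24 trials per
scene, rt_base 500 msec, λ = 50 msec per unit margin, σ_rt = 30 msec,
8 stages. These sizes and the RT scale are chosen to resemble a typical
scene-categorization EEG session (tens of trials per stimulus, ~500 msec
responses, decodable but not saturated category signal).

Seeding: one global seed expands into counter-keyed substreams
(`SeedSequence((seed, stage, participant, repeat))`), so outputs are
bit-identical regardless of evaluation order or parallelism.

**What the generator does not emulate** — and hence what passing tests do
and do not show about real recordings: the category signal is
one-dimensional (all scenes project on one channel pattern, scaled by
their margin), so scene-identity decoding of same-category scenes rests
entirely on margin differences rather than idiosyncratic scene patterns;
there are no artifacts, eye blinks, drifts or bad channels; noise is
Gaussian and stationary; RTs are Gaussian around the linear linking rule
rather than skewed as real RT distributions are; and the monotone
distance–RT link is *assumed* by construction — the simulations validate
that the pipeline recovers such a link when present and stays quiet when
absent, not that the link holds in any particular dataset. The Gaussian
margin and noise choices are stand-ins: no explicit generative model
beyond the monotone distance–RT assumption is established in the
literature the statistic comes from.

## Validation-suite sizes

The test suite and `scripts/acceptance.py` run the full chain at sizes
chosen to keep a complete run on one CPU in the minutes range while
leaving the statistical checks well-powered: the standard design with
5 decoding repeats and 5 replicate seeds for effect recovery, 3 repeats
and 10 (suite) / 3 (script) replicate seeds for null calibration,
n_perm = 2000 for permutation tests, and reduced designs (5–6
participants, 6–8 scenes) for the decoding sanity and searchlight
checks. Chance-level assertions use a binomial band computed from a
deliberately conservative count (one repeat's worth of independent test
evaluations) because repeated evaluations of the same trials are not
independent. Strong-signal checks evaluate bins where the planted
amplitude a(t) ≥ 0.5, since the raised-cosine profile is by construction
at chance at the window edges.

## Known limitations

* The equalize-per-repeat-globally and whitener-outside-folds choices
  (flagged above) are pragmatic conventions; both alternatives would be
  straightforward to add.
* The searchlight treats layout coordinates as flat 2-D; real electrode
  geodesics differ.
* `decode_identity` is O(pairs × folds × bins × repeats) SVM fits and is
  the most expensive stage; use `time_indices` to restrict latencies when
  mapping large designs.
* Pearson r on integer network RTs (readout) is coarse for small stage
  counts; rank statistics could be substituted but would change the
  threshold-selection semantics.
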