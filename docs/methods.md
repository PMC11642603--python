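# Methods

`dyaddraw` simulates and analyses a paired drawing task: a participant and a
virtual partner each draw a half circle or a half diamond from a start point
to an end point directly below it, either **jointly** (the participant must
reach the end point simultaneously with the partner) or **in parallel**
(the participant keeps a consistent ~2 s pace regardless of the partner).
Crossing the participant's and the partner's cued shapes gives four
combinations (CC, DD, CD, DC; first letter = participant) and a congruency
factor (CC/DD congruent, CD/DC incongruent).  The package asks two
questions of the synthetic data it generates: does observing an incongruent
movement distort the participant's drawing more when acting in parallel
(visuomotor interference, VMI), and does the upcoming action information
become less linearly decodable from delay-period EEG when acting jointly
(an "integrated" dyadic representation)?

## Task simulation

**Design.** Per social context, `n_blocks_per_context = 6` blocks of
`trials_per_block = 48` with `catch_per_block = 8` catch trials (the partner
draws the non-cued shape), i.e. 576 trials in total, 60 non-catch trials per
context x combination cell, cue pairs balanced within every cell.  Partner
drawing durations are uniform on 1.8-2.2 s (Joint) and 1.6-2.4 s (Parallel);
the partner's start is jittered +/-100 ms; starts beyond 800 ms would count
as errors; the Joint synchronisation criterion is a 200 ms end-point delta.
Simulated timing behaviour: Joint end-point deltas ~ N(0, 50 ms); Parallel
drawing times ~ N(1.95 s, 0.15 s) (a mild systematic shortening of the
instructed 2 s, as compliant-but-imperfect participants show); catch trials
are detected with probability 0.93.

**Pen trajectories.** Ideal shapes run from (0, 0) to (0, 1200) px, bulging
rightward: the half circle is the semicircle over the start-end diameter;
the half diamond is two segments through the apex at half height with the
same maximal lateral extent (600 px).  A trial's trajectory samples its
ideal shape uniformly in arc length at 30 Hz over the trial's drawing
duration, adds smoothed Gaussian motor noise (`base_noise_sd = 8` px,
tapered to zero at the pinned endpoints), and, on incongruent trials, an
additive lateral pull toward the partner's shape: the normalised difference
field between the two ideal shapes scaled by a per-(context, congruency)
`vmi_shift` (defaults 4 px Joint-incongruent, 14 px Parallel-incongruent —
interference present in both contexts but stronger in parallel).  With
probability `swap_rate = 0.01` the opposite shape is drawn; with probability
`gross_error_rate = 0.01` the trajectory is replaced by a random-walk
scribble.

**EEG.** Epochs are condition-mean spatiotemporal patterns plus Gaussian
noise: 64 channels x 2 s at 128 Hz, `noise_sd = 1` per sample, and a
channel-shared noise component mixed in with weight `spatial_corr = 0.3`.
Patterns are random smooth rank-2 channel x time fields with unit Frobenius
norm, scaled by a single SNR knob `amp`.  In the **integrated** preset the
Joint context gives CC and DD distinct patterns A and B while CD and DC
share one merged pattern (plus a dedicated integration component); the
Parallel context is additive, own-shape component + partner-shape component.
The default `amp = 1.5` was chosen so that group-mean decoding accuracies
span roughly 0.55-0.85 across contrasts — moderate, clearly-above-chance
decoding for the decodable cells with robust recovery at 20 subjects; no
published value constrains this knob, so it is a calibration choice of the
generator.  Channel positions come from a synthetic concentric-ring layout
(generated in code; it is not a standard montage file) — sufficient for the
Delaunay adjacency the spatial statistics need.

## Trajectory pipeline

1. **Resampling.** x and y are interpolated separately as cubic splines of
   the sample index (scipy defaults, not-a-knot boundaries) and evaluated at
   100 equally spaced index values.  Fewer than 4 samples is a degenerate
   trajectory.
2. **Gross-error screening.** An automated proxy for visual inspection: a
   trajectory is discarded if its path length exceeds 2x the cued ideal
   shape's arc length, or if its maximum pointwise distance from *both*
   ideal shapes exceeds 300 px.  Both thresholds are configuration-exposed.
3. **Swap errors.** x is fitted as a function of y (paths run top to
   bottom; y is made strictly monotone by an infinitesimal jitter) with a
   degree-1 and a degree-2 least-squares spline, one interior knot at the y
   of the rightmost point (first occurrence on ties).  The C1 quadratic
   spline cannot reproduce the diamond's corner, so lower linear residual
   means diamond and lower quadratic residual means circle; equal residuals
   (a probability-zero event) label circle with a warning.  A classified
   shape disagreeing with the cue is a swap error and is discarded.
4. **Templates and distortion.** Per participant and shape, the template is
   the pointwise mean of all retained resampled trajectories, pooled over
   conditions.  The VMI score of a trial is the unsigned area enclosed
   between its trajectory and the matching template: the closed polygon
   (trajectory + reversed template) is split at the curves' crossing points
   and absolute sub-loop areas are summed, so distortion is nonnegative and
   never cancels.  The implementation splits index-aligned quads exactly at
   segment intersections; it assumes the two curves are index-aligned,
   which resampling onto a common index grid guarantees.  Tests verify it
   against dense numerical integration (0.5%) and against an independent
   polygonization oracle (machine precision).
5. **Box-Cox.** Area scores are Box-Cox transformed (profile-likelihood
   lambda) before normal-theory modelling; skewness and kurtosis of the
   transformed sample are reported.

## Inference on behaviour

- Catch accuracy Joint vs Parallel: Wilcoxon signed-rank (exact null for
  n <= 25 after dropping zero differences — Wilcoxon's original treatment),
  with CLES defined as the paired P(a_i > b_i), ties counting one half.
- Joint delta times vs 0 and Parallel drawing times vs 2 s: one-sample
  t-tests with Cohen's d and a JZS Bayes factor (Cauchy prior, scale
  0.707, computed by numerical integration; cross-checked against
  pingouin in tests).
- **Congruency effect** = mean(incongruent) - mean(congruent) distortion
  per subject and context, computed on the Box-Cox scale (the scale the
  mixed model uses; the raw-area alternative gives the same sign).  The
  directional test is a one-tailed paired t across subjects
  (Parallel > Joint).
- **Mixed model**: Box-Cox area ~ context * congruency with a random
  intercept per subject, sum coding (-1, 1), REML via statsmodels MixedLM.
  The response is standardised internally for optimizer conditioning and
  estimates are mapped back (t, df, p are invariant).  Satterthwaite
  degrees of freedom are computed in-package: the coefficient-variance
  gradient and the variance-component Hessian of the per-group REML
  profile log-likelihood are obtained by central finite differences
  (forward at the tau^2 >= 0 boundary); df_j = 2 var_j^2 / (g' A g).  A
  non-convergent fit raises; nothing silently substitutes residual df.
  One test reproduces lmerTest's estimates, Satterthwaite df and p-values
  on simulated data.
- **Error-count models**: Poisson GLMs of per-subject, per-cell gross and
  swap counts with the same sum-coded factors; Wald p-values; diverging
  coefficients or standard errors flag separation/instability.

## Decoding pipeline

Per subject, contrast and context: usable trials are correctly identified
catch trials plus regular trials without a false alarm.  **Supertrials**
average `n_avg = 4` same-class trials balanced across the two cue pairs —
combination contrasts (CD vs DC, CC vs DD) take two trials per cue pair of
one condition; own/partner-movement contrasts take one trial from each
condition x cue-pair cell of the class.  Ten supertrials per class are
sampled without replacement within a permutation (fresh sampling across
permutations).  Each supertrial is demeaned per channel and averaged into
10 half-open 200 ms bins over 0-2 s; at 128 Hz a bin holds 25 or 26 samples
(time-defined binning).  64 channels x 10 bins = 640 features.  Demeaning
and binning are linear, so the implementation precomputes per-trial binned
features and averages them per supertrial — algebraically identical to
binning the demeaned supertrial, and an order of magnitude faster.

The classifier is a binary LDA whose pooled covariance is the
prior-weighted average of per-class Ledoit-Wolf-shrunk covariances
(estimated on standardised features and rescaled) and whose weights solve
S w = mu_1 - mu_0.  It is written as closed-form numpy because the
permutation pipelines perform ~10^5 fits; tests require its decision
values to match the reference library estimator (lsqr solver, automatic
shrinkage) to 1e-8.  Accuracy comes from stratified 5-fold
cross-validation (training sets of 16, test sets of 4, both classes
equally represented; folds re-randomised per permutation), averaged over
`n_perm = 100` permutations (empirical) or over permutations with
balanced random class assignment of the supertrials (null).  Group
inference: one-tailed paired t-tests of empirical vs null per contrast,
two-tailed paired t-tests of empirical accuracies between contexts.

Seeding is counter-based: every permutation's generator is derived from
(master seed, contrast, context, empirical/null tag, permutation index),
so runs are bit-reproducible and empirical/null streams are independent.

### A structural limit of the integrated preset

With pattern(CD) = pattern(DC) = X, pattern(CC) = A, pattern(DD) = B in
Joint, the own-movement contrast ({CC,CD} vs {DC,DD}) and the
partner-movement contrast ({CC,DC} vs {CD,DD}) both reduce to supertrial
class means (A+X)/2 vs (B+X)/2 — identical class-conditional
distributions — so any classifier yields the same expected accuracy for
both.  More generally, own-separation minus partner-separation equals the
CD-DC separation, so "own decodable, partner at chance" would require the
incongruent contrast to be strongly decodable, contradicting integration.
An additive mean-pattern generator therefore cannot reproduce the full
qualitative matrix in which the partner's movement alone is at chance in
Joint while one's own movement is decodable; human data evidently are not
an additive mean-pattern process.  The package implements the preset as
defined (exact sharing); in the recovery experiment every cell of the
matrix reproduces except partner-in-Joint, which decodes exactly as well
as own-in-Joint, and the corresponding acceptance assertion fails by
design rather than being weakened.

## Spatial decoding

The channelwise analysis reuses the identical supertrial/CV/permutation
machinery with each channel's 10 temporal bins as the only features (the
per-channel feature set mirrors the spatiotemporal pipeline), one
accuracy per channel, subject and contrast.  Group inference is a
cluster-based permutation test: per-channel one-sample t vs chance (0.5),
thresholded at the two-sided-equivalent critical t for p = 0.05 applied
above-chance only (only above-chance decoding is meaningful for accuracy);
supra-threshold channels are clustered under the Delaunay adjacency of the
montage; the cluster statistic is the summed t; the null is the maximum
cluster statistic over 1000 random per-subject sign flips of
(accuracy - chance).  No supra-threshold channel is a valid empty result.
Cluster p-values use the (b+1)/(m+1) permutation convention.

## Numerical and design choices

- Ledoit-Wolf shrinkage is always in [0, 1] (property-tested); the pooled
  covariance solve falls back to least squares if singular.
- Stratified folds error out when a class has fewer members than folds;
  supertrial sampling errors name the deficient design cell.
- The area routine treats zero-area elements as part of the current
  sub-loop run; per-edge cross products are computed before summation so
  identical curves give exactly zero.
- Distance to an ideal curve is a nearest-vertex query on a 2000-point
  dense polyline (KD-tree), accurate to ~0.6 px — ample for the 100 px
  corridor band and the 300 px screening ceiling.
- The trial screening keeps the same expected retention fraction in every
  design cell when generator effects are cell-symmetric; the error-count
  GLMs are the check used on real data.

## Problem sizes in the test and acceptance suites

Generator defaults stay at the published task scale.  The stochastic
suites run at reduced sizes chosen to keep the whole test run in the tens
of minutes on one CPU: null calibration uses 200 experiments of 6 subjects,
8 channels, 4 blocks/context and 20-permutation pipelines; the
integration-recovery experiment uses 20 subjects, 16 channels and 20
permutations; VMI recovery uses 100 simulations of 20 subjects with one
block per context (20 trials per context x congruency cell) and a planted
10 px pull; cluster-inference calibration uses 200 null experiments of 15
subjects at 300 sign-flip permutations.  The acceptance script runs the
full end-to-end study at 8 subjects, 16 channels and 10 permutations.
Reduced channel counts shrink the feature space (channels x 10 bins) but
leave every pipeline stage and statistical property intact.

## What the synthetic data do and do not show

The generator reproduces the design arithmetic, the timing rules, the
screening structure and configurable pattern separability, so passing
tests demonstrate that the pipeline recovers planted effects and stays
calibrated under null conditions at realistic sizes.  It does not emulate
ongoing oscillations, eye or muscle artifacts, preprocessing residue,
learning or fatigue across blocks, or kinematic detail beyond the
deflection model — so the tests say nothing about robustness to those
properties of real recordings, only about the correctness and calibration
of the analysis itself.
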