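# Methods

This note documents the statistical procedures implemented in `eegdecode`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish.

## Data model

A subject's data is a mapping `(run, condition) → array` of shape
`(timepoints, channels, trials)` in microvolts, with 1-based contiguous
run/condition indices (matching the common MATLAB cell-array export of
epoched, condition-sorted ERP data). All cells must share timepoint and
channel counts. Preprocessing (filtering, artefact handling, epoching,
baseline correction) is assumed done upstream; the package never modifies
amplitudes except by windowing and averaging.

Window parameters are given in milliseconds and converted by
`round(ms · rate / 1000)`; a non-integral sample count is an error rather
than being silently rounded, because silent rounding would change the
analysis grid. Windows that would extend past the epoch end are dropped,
never truncated, keeping feature dimensionality constant across steps.

## Decoding procedure

Per analysis window and discrimination group:

1. **Extraction.** Spatial mode: the within-window time-average per
   channel (`n_channels` features). Temporal mode: the raw samples of one
   chosen channel (`width` features). Spatiotemporal: all samples of all
   channels in channel-major order (`n_channels · width`); the fixed
   ordering matters because weights are later averaged per channel.
   Amplitudes enter the classifier raw; an optional per-feature z-scoring
   flag (train-set statistics applied to the test set) exists but defaults
   off, since standard practice for ERP amplitude decoding is unscaled
   input.
2. **Balancing.** Conditions are subsampled (uniformly, seeded) to the
   smallest condition count. The subsample is re-drawn inside every
   repetition so exclusion noise averages out.
3. **Cross-validation.** Per condition, exemplars are randomly divided
   into k equal sets (`floor(n/k)` each; the `n mod k` left-overs are
   excluded for that cycle). Each set serves once as test data. The cycle
   is repeated m times with fully independent draws; the window score is
   the grand mean of all m·k analyses. Defaults k = m = 10.
4. **Backend.** A linear soft-margin C-SVM (C = 1) for classification and
   linear ε-SVR (C = 0.1) for regression, via scikit-learn's libsvm
   bindings. Multi-class problems use one-vs-one voting with ties broken
   toward the lowest class index. Any estimator with `fit`/`predict` can
   be injected for testing.
5. **Scoring.** Classification: percent of correctly labelled test
   exemplars. Regression: Fisher-Z (artanh) of the Pearson correlation
   between predicted and true labels, with r clamped to ±(1 − 1e−12) so a
   perfect fit maps to a large finite value; an undefined correlation
   (constant predictions or labels) scores 0 and increments a
   degenerate-score counter on the result.

**Block averaging** (optional) replaces each run's trials by their mean
before balancing, trading exemplar count for signal-to-noise.
**Cross-condition decoding** trains on all balanced exemplars of one
condition context and tests on a disjoint context; train and test are
already independent, so no k-fold split is used and only balancing is
re-drawn across the m repetitions.

### Permuted-label analyses

The empirical chance distribution repeats the identical analysis — same
data, same balanced subsample, same set assignment — with labels
re-shuffled independently in each repetition. Labels are shuffled **within
each cross-validation set**, not across the whole sample. Globally
shuffled labels leave total counts intact but create complementary class
imbalances between training and test folds; a linear SVM then leans
toward the training majority class, which is the test minority class, and
the chance estimate lands systematically 2–4 % *below* the theoretical
level at realistic trial counts. Within-set shuffling preserves exact
per-fold class balance, destroys the label–data association just the
same, and centres the empirical chance distribution on the theoretical
level — which is the behaviour the method's validation requires.

### Seeding

One master seed governs an analysis. Child generators are derived
deterministically per (window, repetition, purpose) via seed-sequence
spawn keys, so real and permuted analyses are reproducible independently
and results are invariant to execution order.

## Feature weights

Linear-model weights are extraction filters, not topographies: a channel
can carry weight purely to cancel noise shared with informative channels.
Each fold's weight vector w is therefore transformed into an activation
pattern `a = Σₓ w / Var(wᵀx)` using that fold's training covariance Σₓ
(the single-component forward-model transformation). Corrected (and raw)
weights are averaged, signed, over all m·k analyses first — averaging
before rectification suppresses noise that would otherwise survive the
absolute value — then averaged over each channel's window timepoints,
rectified, and z-standardised across channels within each window. If the
across-channel SD vanishes the z-scores are defined as 0 (with a warning)
rather than NaN. A degenerate activation pattern (zero projected variance
in one fold) contributes a zero vector instead of aborting. Channel-level
maps are defined for spatial and spatiotemporal analyses only; temporal
mode has a single channel.

## Group statistics

Subjects contribute window-wise mean accuracies. The chance reference is
either the theoretical level (100/c %) or, preferably, each subject's mean
permuted-label accuracy (their full permutation distributions are kept for
prevalence inference; the mean is used for the paired test because a
paired test needs one reference value per subject).

- **Student paired t** on the differences, one-sided above chance by
  default (above-chance decoding is the hypothesis; two-sided available).
- **Yuen paired t**: 20 % trimmed mean of the differences over the
  winsorised standard error `sqrt(s²_w (n−1) / (h(h−1)))`, `h = n − 2g`
  effective observations, df = h − 1. Robust against the non-normality
  typical of accuracy scores; trimming proportion configurable.
- Zero-variance differences yield t = 0, p = 1 with a warning.

Multiple-comparison corrections across windows:

- **Holm–Bonferroni** and **FDR** (Benjamini–Hochberg; two-stage adaptive
  variant) via statsmodels, verified in the test suite against
  independently coded step-down/step-up oracles.
- **Maximum statistic**: null distribution of the per-permutation maximum
  t under random within-subject sign flips of the difference scores; the
  observed labelling is always included as one permutation.
- **Cluster-based**: temporally adjacent windows with uncorrected
  two-sided p below the cluster-forming threshold (default 0.05) form
  clusters with mass = summed t, compared against the permutation
  distribution of the maximal cluster mass. Exploits the temporal
  autocorrelation of decoding time courses to preserve power.
- **Generalised FWER (u = 1)**: single-step variant thresholding at the
  (1 − α) quantile of the (u+1)-th largest sign-flip statistic. This
  controls P(more than u false rejections) ≤ α; the iterative step-down
  refinement adds power, not validity, and is not implemented.

### Prevalence (minimum statistic)

Each subject supplies their observed accuracy plus m first-level
permutation values (one per permuted repetition, each a k-fold mean; the
observed value is added as one more permutation). Second-level Monte-Carlo
resampling draws one first-level value per subject and takes the minimum
across subjects; the global-null p-value is the fraction of draws whose
minimum is at least the observed minimum (the all-observed combination is
always counted, so p ≥ 1/(N+1)). The prevalence lower bound is the largest
majority fraction γ for which `[(1−γ)p^{1/N} + γ]^N ≤ α`, i.e.
`γ* = (α^{1/N} − p^{1/N}) / (1 − p^{1/N})`, clipped to [0, 1] and 0
whenever the global null is not rejected.

Note an intrinsic limitation of the minimum statistic: subjects without
information contribute chance-level minima that are exchangeable with
their own permutations, so with a fraction q of null subjects the global
null is rejected with probability at most α^q regardless of sample size —
about 0.22 at α = 0.05 when half the group is null. The prevalence bound
is correspondingly conservative for heterogeneous populations. This is a
property of the method, not of this implementation, and one acceptance
check that presumes majority rejection under 50 % heterogeneity is
accordingly expected to fail.

### Group feature weights

Per-channel maps are averaged over user-selected windows, tested per
channel against zero (one-sided, Student or Yuen), and corrected across
channels by any of the methods above.

## Synthetic data

The generator emulates the validation design used throughout the tests:
i.i.d. Gaussian noise (mean 0, SD 1) for every timepoint × channel ×
epoch, with a constant signal added to a channel subset over a timepoint
range in signal conditions (defaults: 64 channels, 100 timepoints, signal
on channels 1–10 at timepoints 51–100; signal sizes 0.05–0.3 are probed in
the acceptance tests, 1000 epochs in the original protocol, 200 at desk
scale). Group studies use independent per-subject seeds; a heterogeneity
fraction silently zeroes the signal for a trailing subset of subjects for
prevalence ground truth. An SVR variant scales the signal block by a
uniformly drawn per-trial label.

Temporally independent noise is *not* realistic EEG: real data have
autocorrelated, spatially correlated, non-stationary noise. A green test
on this generator establishes the correctness of the pipeline's
bookkeeping and statistical calibration, not robustness to realistic noise
structure. An optional AR(1) coefficient (stationary, unit marginal
variance) is available for stress tests and defaults off.

## Numerical and tolerance choices

- Fisher-Z clamp: |r| ≤ 1 − 1e−12.
- Degenerate z-scoring cutoff: across-channel SD ≤ 1e−12 relative to the
  mean magnitude.
- Monte-Carlo assertions in the test suite use windows computed on
  disjoint timepoint ranges as independent units and allow 3 standard
  errors; all stochastic tests are seeded and therefore deterministic.
- Type-I error checks run 200 simulated null group studies (12 subjects,
  pure noise, 4 windows, k = 3, m = 1, 200 sign-flip permutations) — a
  deliberately reduced scale chosen to keep the suite within CI budgets
  while leaving ~1.5 % Monte-Carlo SE on the rejection-rate estimates.

## Known limitations

- No temporal-generalisation (train-time × test-time) matrices.
- No frequency-domain or component-space inputs, and no preprocessing.
- Channel maps are plotted without scalp interpolation; with no electrode
  coordinates the display degrades to an ordered bar strip.
- Nonlinear kernels are not exposed; the validated path is linear only.
- The prevalence bound inherits the minimum statistic's conservatism for
  heterogeneous populations (see above).
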