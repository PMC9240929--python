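# Methods

This note records the statistical model behind `fairaudit`, the defaults
and the reasoning for them, and the places where a genuinely open design
choice had to be made.

## The audit model

The unit of analysis is a cohort table: one row per participant with a
binary protected attribute S (privileged level: men), a vector of
real-valued phone-usage features, a continuous mental-health score, and a
binary label obtained by a median split of the score (label 1 iff score >
median; scores exactly at the median get 0 — a deterministic tie rule that
also resolves the degenerate all-equal case to all-0). A mean split is
available as an option, since dichotomization "above or below the center"
is reported both ways in the sensing literature.

One audit **iteration** is a stratified 5-fold cross-validation of the
cohort, reshuffled with seed `base_seed + iteration`. Folds are stratified
on the joint (label × group) cell whenever every nonempty cell has at least
`n_folds` members, otherwise on the label alone; without joint
stratification, small cohorts (n≈55, 38% minority) routinely produce folds
in which a group metric is undefined. Inside each training fold, and
strictly inside it, the pipeline:

1. optionally fits and applies the disparate-impact repair (see below);
2. computes feature medians, imputes, standardizes (zero-variance features
   get scale 1 with a logged warning);
3. balances the classes with SMOTE (k = 5 neighbors, reduced to
   minority−1 when the minority is smaller; test folds keep their original
   class ratio);
4. fits a PCA on the balanced standardized matrix and keeps the top 5
   components (when the matrix has rank below 5, the smallest component
   count reaching 99% explained variance);
5. trains the classifier.

The held-out fold is transformed with train-fitted parameters only.
Out-of-fold predictions are pooled across folds before any metric is
computed — per-fold group cells are too small to score on their own. An
iteration in which a metric is undefined (a zero denominator) is recorded
as skipped with its reason and excluded from aggregates; an audit aborts if
more than half its iterations skip.

The pipeline order impute → standardize → SMOTE → PCA is one of several
defensible readings of the usual narrative descriptions; it is the default
and configurable (`smote_before_pca=False` fits the PCA on the unbalanced
matrix). SMOTE itself is implemented in-package (interpolation on segments
to one of the k nearest minority-class neighbors, originals preserved as a
prefix, seeded); nearest-neighbor search is delegated to scikit-learn.

Classifier hyperparameters are frozen library defaults except the random
forest (100 trees, maximum depth 6) — the audit studies group disparity,
not tuning. The SVM uses the RBF kernel, recorded in the run manifest.

## Fairness metrics

All metrics are computed from per-group confusion counts. Differences are
reported as privileged − unprivileged in percentage points (positive =
favours the privileged group); SPD follows the same sign convention with a
flag to flip it. Disparate impact is the unprivileged/privileged ratio of
positive-prediction rates, flagged at the conventional 0.8 threshold. The
balanced error rate is the *mean* of the two group error rates — the form
consistent with its standard use and with the sacrificed-minority example
(overall error 0.1, BER 0.5); a subtraction-based variant sometimes appears
in print but cannot reproduce that example. Undefined metrics raise
structured errors rather than returning NaN so the harness can count skips.
Delta accuracy is aggregated both signed and as the mean of per-iteration
absolute values; the absolute version is what a "delta across gender"
column in a results grid reports.

## Significance testing

Group comparisons use a nonpaired two-tailed t test, Welch by default
(pooled-variance optional). Two tests are attached to every audit:

- **iteration-level** — Welch t on per-iteration privileged vs unprivileged
  accuracies. This is the test conventionally printed in audit tables, but
  the iterations share one cohort, whose realized group difference is a
  fixed effect; the test therefore overstates significance (on null cohorts
  it rejects far above its nominal level) and should be read as
  descriptive.
- **participant-level** — Welch t comparing per-participant mean
  out-of-fold correctness between the groups. Participants are the
  independent units, and on unbiased synthetic cohorts this test holds its
  nominal 5% size (measured 5.6% over 500 replicate audits of fresh
  null cohorts, 10 iterations each, n=200).

## The disparate impact remover

For each feature and group the fit stores the sorted training values; the
target quantile curve is the median across groups (with two groups, the
midpoint) of per-group quantile curves on a fixed 101-point grid with
linear interpolation. Application maps a value x in group g to
(1−λ)·x + λ·q̄(F_g(x)), where F_g is the interpolated empirical CDF
(sorted values against plotting positions 0 … 1). This continuous CDF —
rather than a step-function rank/n — is what makes the map strictly
monotone on the fitted range (ranks preserved for every λ) and makes λ=1
exactly congruent on matched group sizes: {1,2,3} and {11,12,13} both
repair to {6,7,8}. Values outside a group's fitted range clamp to the
0th/100th percentile quantiles. Repair operates on raw features before the
preprocessing chain, labels and the protected attribute are never touched,
and the protected attribute is never given to the classifier as a feature —
the repair targets exactly the indirect pathway through the features. The
default repair amount is λ=1 (full repair), with partial repairs available
for utility/fairness trade-off sweeps.

## The synthetic cohort generator

The generator emulates the statistical structure described for small
phone-sensing mental-health cohorts; it does not simulate raw call logs or
survey instruments (feature names are positional). Each participant has a
5-factor latent behavioural state z ~ N(0, I). Features are noisy linear
mixtures of z (mixing matrix with unit-norm columns drawn once per seed;
feature noise SD 0.1, which makes the top-5 principal components of a
default cohort explain >99% of variance). Group structure enters in two
controllable ways:

- **group_shift** — minority participants are shifted down along the
  score-index direction in latent space, scaled so per-feature
  standardized mean differences have RMS ≈ `group_shift`. Placing the
  shift along the behavioural axis that predicts the score is both the
  realistic reading (gendered usage differences live in the same behaviors
  that carry the mental-health signal, which is why a pooled threshold
  misreads one group) and the property that makes the induced bias robust:
  a shift orthogonal to the signal is trivially decodable, and at n≈200
  even a linear classifier then fully compensates, leaving nothing to
  audit.
- **legacy_strength** — the score is a positive linear index of the
  *group-centered* latent state (a within-group percentile means the same
  thing in either group — the generator's version of percentile-based
  worthiness), minus `0.2 × legacy_strength` (index-SD units) for minority
  members, plus N(0, noise_sd²) noise. The offset is the *negative legacy*:
  it thins high-score labels in the minority group. With
  `legacy_strength = 0` the score, and hence a median-split label, is
  independent of group even when feature distributions differ.

Defaults (n=55, 38% minority, 10 features, shift 0.6, legacy 0.7,
noise_sd 0.3, legacy scale 0.2) were fixed once so that audited cohorts
reproduce the qualitative bias regime reported for such studies — overall
accuracy near 80%, baseline disparate impact well below the 0.8 threshold,
a double-digit accuracy gap favouring the privileged group — while full
repair returns disparate impact to ≈1 and at least halves the mean absolute
accuracy gap. They were not adjusted afterwards.

What passing tests show, and what they do not: the generator's cohorts are
Gaussian, stationary, and missing-complete-at-random (missingness is
injected independently per cell only when asked). Real sensing cohorts have
heavy-tailed usage features, informative missingness, and label noise
correlated with behaviour; results here demonstrate the pipeline's
*mechanics* (leakage-free evaluation, metric correctness, repair behaviour),
not that any particular real dataset is or is not biased.

## Numerical and scale choices

- Quantile grid: 101 points, linear interpolation; configurable.
- Median of two quantile curves = midpoint (even-count median), making the
  two-group repair symmetric.
- Seeds: every stochastic step (generation, shuffling, SMOTE, classifier)
  is derived from explicit seeds; an audit is a pure function of (cohort,
  config). Derived seeds are reduced mod 2³¹.
- Calibration/recovery checks run at reduced problem sizes chosen as the
  package's own test design: type-I calibration uses 500 replicate audits
  of 10 iterations each (n=200, logistic regression); the
  detection-then-mitigation check uses 20 cohorts × 20 iterations. At
  n=200 the mean per-iteration |Δaccuracy| of a perfectly fair classifier
  has a finite-sample floor near 4 percentage points (the expected absolute
  value of a mean-zero group difference), which is why mitigation is judged
  as a ≥50% reduction rather than convergence to zero.

## Known limitations

- Binary protected attribute and binary label only; no nonbinary gender
  modelling, no multi-attribute or intersectional audits.
- Preprocessing-only mitigation; in-processing and post-processing families
  are out of scope.
- The iteration-level t test is reported for comparability but is
  anticonservative by construction; use the participant-level test for
  inference.
- `apply_repair` requires complete features; the harness imputes missing
  cells with train-fold medians before repairing, but direct use of the
  repair API on incomplete tables raises.
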