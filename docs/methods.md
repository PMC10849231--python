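# Methods

## The problem splitaudit addresses

Clinical machine-learning studies are frequently limited to a few hundred
cases with a low-prevalence outcome. When such a pool is split once into a
training and a test arm, both reported numbers — the cross-validated
training AUC and the held-out test AUC — are functions of one random
partition. Because the pool is fixed, the two arms are complementary
samples: cases that make the test arm "easy" are, by construction, missing
from the training arm. Repeating the shuffle-split therefore produces
train/test AUC pairs that spread *perpendicular* to the identity diagonal,
and a single published pair can sit anywhere on that anti-diagonal.
splitaudit packages the machinery to measure this: repeated
prevalence-balanced splits, a faithful nested-CV training procedure, the
tradeoff regression, covariate-balance monitoring, and incremental-cohort
learning curves.

## Synthetic cohort generator

No suitable public dataset exists at this design point (case-level tables
with ~16% prevalence, two device strata and a hundred-odd correlated
features), so the package carries a generator whose ground truth is known
analytically.

Features are class-conditional multivariate Gaussians with a shared
equicorrelated covariance `Sigma = (1-rho) I + rho 11'` (default
`rho = 0.3`, unit variances). For two Gaussian classes separated by
Mahalanobis distance `d`, the optimal linear discriminant
`w = Sigma^{-1} (mu1 - mu0)` has population AUC

    AUC = Phi(d / sqrt(2)),

so the class-mean difference is rescaled to hit any target AUC exactly
(default 0.70, the scale of discriminability reported for this kind of
upstaging task). The effect is spread over a subset of informative
features (default 20 of 109 "radiomic" and 3 of 4 "clinical" features);
the rest are pure correlated noise, giving feature selection something real
to find. Defaults follow the audited study design: 700 cases, prevalence
0.163 (exactly 114 positives by round-half-up), two vendors in equal
proportion.

Vendor membership is independent of the outcome and acts only as a fixed
location/scale offset on all features (defaults: +0.3, x1.15 for the second
vendor). Per-vendor standardization therefore genuinely matters, but
carries no label information — matching a design in which devices differ
in feature calibration, not in case mix. Age and lesion size are drawn from
class-specific normals (age 62 vs 66 y, SD 10; lesion size 12 vs 16 mm,
SD 6/8) — magnitudes chosen so that per-split balance tests flag only
occasionally, i.e. the covariates are real but weak confounders.

What the generator deliberately does **not** emulate: non-Gaussian and
heavy-tailed feature distributions, vendor-by-label confounding, missing
data, label noise, and heterogeneous per-case difficulty beyond what the
Gaussian model induces. Consequences: passing tests show that the audit
machinery recovers the qualitative phenomena (anti-diagonal tradeoff,
balance-test calibration, learning-curve narrowing) under a clean,
well-specified data-generating process; they do not certify absolute AUC
levels for any real dataset, and real data with more heterogeneous case
difficulty should show these phenomena more strongly, not less.

## Resampling design

Each shuffle-split allocates positives proportionally:
`train_pos = round(n_pos * n_train / n)` with exact integer arithmetic and
half-ties rounded down; a 700-case pool with 114 positives split 400/300
yields (65, 335) / (49, 251). Positives and negatives are permuted
separately with per-split seed `master_seed + split_id (mod 2^31)`, so any
split is re-creatable in isolation. The default is 50 splits, configurable.

Per split, Welch two-sample t-tests compare age and lesion size between
arms at alpha = 0.05 without multiplicity correction — each split is
flagged on its own, which is how imbalance is monitored in practice. Under
a random partition of a fixed pool the test is calibrated: the
per-covariate flag rate matches alpha (verified over 1000 splits).

## Training procedure

Training on one arm is `n_repeats` x (stratified `k`-fold CV with an inner
selection loop): default k = 5 and 200 repeats, with the repeats
reshuffling fold membership to wash out case-ordering effects. Within each
outer fold, an inner stratified 3-fold CV evaluates the hyperparameter
grid — for L2-regularized logistic regression one C per decade from 1e-10
to 1e10 (21 points) — and the best inner validation AUC wins, ties going to
the stronger regularization. The outer-fold model is refit with the winning
configuration on the outer-training portion and scored on the held-out
fold; the training result is the mean over all repeats' fold-mean AUCs.
Per-vendor standardization is refit inside every outer-training portion, so
no held-out statistic leaks into any fit.

Every inner win is a *selection event* (k x n_repeats events total). The
final model uses the modal hyperparameter across events and — under
stability selection — the features kept in at least 50% of events, where
each event keeps the top-20 features by absolute standardized coefficient
of its winning refit. "Stability selection" has no unique definition in
the radiomics literature; selection-frequency thresholding across resampled
fits is the reading implemented here, and both the per-event size and the
threshold are configuration values. The final model (standardizer +
classifier) is then fit once on the entire training arm: one fixed model
for testing, serializable and applied to test cases with zero refitting.

SVMs are supported with a grid over kernel (linear preferred before rbf),
C (1e-3..1e3 per decade) and rbf kernel coefficient (1e-3..1e1 per decade);
decision scores, not probabilities, feed the AUC, so calibration is
irrelevant to the rank-based estimator. Stability selection is restricted
to the logistic model, where coefficients are well-defined.

### Numerical choices

- AUC is the Mann–Whitney estimator (ties counted 1/2), identical to the
  trapezoidal ROC area; computed by `sklearn.roc_auc_score` at the API
  surface and by an equivalent midrank formula inside the CV hot loop
  (equality is tested against exhaustive pair enumeration).
- The inner C grid is fit as a warm-started regularization path
  (coefficients carried from one C to the next) at optimizer tolerance
  1e-4 — rank-based AUC selection is insensitive to tighter tolerances,
  while contract-level fits (`train_classifier`, final models) use 1e-8.
  When available, scikit-learn's internal warm-started path routine is
  used; otherwise an equivalent public-API loop runs.
- Standardization uses the population (1/n) variance convention,
  configurable to 1/(n-1); zero-variance features within a vendor are an
  error, not a silent epsilon.
- All seeds are derived by documented affine counter schemes modulo 2^31
  (per-split: `master + id`; per-repeat: `seed + repeat`), making every
  subcomputation individually reproducible and the whole pipeline
  bit-deterministic under a fixed config.

## Evaluation

The tradeoff regression is ordinary least squares of test AUC on train AUC
across splits; `pearson_r` carries the sign (negative = anti-diagonal),
and the two-sided p-value tests a zero slope. Paired model comparisons use
a sign-flip permutation test on per-split test-AUC differences (default
1e4 flips, add-one p-value convention), which assumes only exchangeability
of the paired differences under the null.

## Learning curves

Cohorts grow in nested chains: per chain, a prevalence-preserving subset of
`step` cases grows by `step` without replacement until the pool is
exhausted (default step 100, 20 chains), so the full-size set is always the
entire cohort and its spread across chains is exactly zero. An
independent-draw mode redraws each size. Quartiles use the
linear-interpolation convention.

Convergence is declared at the smallest size from which every later
consecutive pair satisfies `|median shift| <= IQR at the larger size`.
One special case: the exhausted full-size point has IQR exactly zero by
construction, which measures nothing about sampling variability, so that
pair is judged against the smaller size's IQR instead.

## Problem sizes used in the shipped experiments

The packaged experiments run the audit at the full design (700 cases,
100 splits of 400/300, 5-fold CV) but with 10 CV repeats instead of 200,
and the learning curve with 2 repeats — the repeat count only smooths the
repeat-average, and these sizes resolve the phenomena cleanly on a single
CPU. Both are plain configuration values; nothing in the code changes at
200 repeats.

## Known limitations

- The equicorrelated Gaussian generator makes per-case difficulty
  relatively homogeneous; the anti-diagonal correlation it produces is
  real but weaker than what heterogeneous clinical data typically shows.
- The stability-selection operator is one defensible formalization among
  several; selection frequencies depend on it.
- No confidence intervals are attached to single-split AUCs (DeLong or
  bootstrap), and no class weighting or probability calibration is
  offered — the audited procedure uses none.
- The inner selection sits per outer fold; alternatives (per repeat, or a
  single outer GridSearch) would tally different event counts.
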