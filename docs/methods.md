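# Methods

This note records the statistical model the package implements, the
defaults and why they are what they are, what the synthetic-data generator
does and does not emulate, and the numerical choices a maintainer would
otherwise have to reverse-engineer.

## Outcome definition

Postpartum glucose tolerance is labelled from up to three screening
measures: fasting glucose (P-FG, mmol/L), 2-h postprandial glucose (P-PG,
mmol/L) and HbA1c (mmol/mol). Under the default NICE rule-set, type-2
diabetes is P-FG ≥ 7.0 ∨ P-PG ≥ 11.1 ∨ HbA1c ≥ 48, and prediabetes is
P-FG ≥ 5.6 ∨ P-PG ≥ 7.8 ∨ HbA1c ≥ 40. WHO drops the HbA1c criterion and
moves the fasting cut to 6.1; ADA lowers the HbA1c cut to 39. All
comparisons are inclusive. Diabetes takes precedence; a woman with no
measure at all is `unlabelled`. A consequence of the OR-rule, adopted
deliberately: a woman with *only* an HbA1c measurement is labelled by that
measurement alone. The two-class modelling outcome is prediabetes (1) vs
normal glucose tolerance (0); diabetes and unlabelled rows are excluded
from model fitting with a logged count. Units are fixed (mmol/L, mmol/mol);
no mg/dL conversion is attempted.

## Synthetic cohort generator

The generator emulates the *statistical* structure of a GDM postpartum
screening cohort: n = 394, prevalence 23.35%, class-conditional Gaussian
moments for the six class-varying features (age, BMI, weight via
BMI·height², A-FG, A-PG, A-HbA1c) and for the three postpartum measures,
cohort-wide marginals for the remaining antenatal/delivery covariates, and
categorical/flag frequencies matching the observed cohort composition.

Two outcome mechanisms are provided because different checks need
different views of the same population:

* **latent-logistic** (default): outcome ~ Bernoulli(expit(b₀ + b₁·A-FG +
  b₂·A-HbA1c)) with (b₀, b₁, b₂) = (−8.36, 0.58, 0.10) on raw units. This
  is the causal direction the composite score assumes and is what
  parameter-recovery tests exercise. At the cohort marginals these
  coefficients imply a rate near 0.13, not the target prevalence, so by
  default an *additive intercept offset* is solved (Brent's method on the
  sampled linear predictor) to hit the target exactly in expectation; the
  slopes — the recoverable quantities — are never touched.
  `calibrate_intercept=False` restores the literal intercept.
* **class-conditional**: outcome first at the target prevalence, features
  from class-specific Gaussians — the mode for moment-matching checks.

A-FG and A-HbA1c are drawn jointly with correlation 0.3 (configurable);
only the marginal moments of the real cohort are known, and 0.3 is a
mid-range value for fasting glucose vs HbA1c in pregnancy. Gaussian draws
are resampled above physiologic floors (glucose > 2 mmol/L, HbA1c > 15
mmol/mol, and analogous floors for the nuisance covariates).

Postpartum measures are drawn from the class-conditional moments and
resampled (deterministic repair after 200 rounds) until the glycaemic
rules recover the assigned class exactly — positives fire at least one
prediabetes threshold and no diabetes threshold, negatives fire none. The
generator asserts this recovery on every draw.

Missingness is missing-completely-at-random per antenatal cell;
outcome-defining postpartum fields are never masked. The generator does
**not** emulate: informative postpartum drop-out (the real cohort lost 213
women to follow-up non-randomly), measurement rounding, within-woman
repeat measures, or covariate dependence beyond the single glucose–HbA1c
correlation. Passing tests therefore demonstrate correctness of the
*pipeline mechanics and estimators under the assumed structure*, not
clinical performance on real screening data.

## Fold-local preprocessing

Chained-equations imputation initializes missing cells at training-column
means, then cycles incomplete features in column order for 10 sweeps,
regressing each on all other features by OLS over the training rows
observed for that feature and replacing its missing cells with
predictions. No posterior noise is drawn: one completed dataset per fold,
fully deterministic (hence row-order invariant — OLS does not care about
row order, and no random draws occur). Models are fitted on training rows
only and replayed on held-out rows; features complete in training get a
single post-sweep regression so held-out missingness in them is still
handled. A feature observed nowhere in the training fold is a hard error.
Columns whose observed values are all 0/1 (one-hot dummies, flags) have
imputations clipped to [0, 1]. Categorical features are one-hot encoded
(first level as reference) *before* imputation; scaling (z-score with
training mean/sd, population sd, constant features flagged and left at
scale 1) happens *after* imputation, both inside the training fold. Single
completion rather than Rubin-pooled multiple imputation is deliberate: the
evaluation aggregates one prediction per held-out sample, so a single
completed dataset per fold is the matching design.

Class weights are exactly w_k = 1/(2·fraction_k), which equalizes total
loss mass across classes (n_k·w_k = n/2) and feeds every learner's
per-sample loss.

## Nested cross-validation

Outer leave-one-out CV assesses the model; an inner stratified 4-fold grid
search on each outer-training fold picks hyperparameters; the winner is
refitted on the whole outer-training fold and the held-out probability
recorded. For the costly ensembles (random forest, gradient-boosted trees)
the outer scheme defaults to stratified 4-fold. All preprocessing is
fitted per fold (both levels), so the held-out sample cannot influence any
imputation regression, scaler statistic or class weight. Within an inner
fold the preprocessing is computed once and shared across grid candidates
— candidates differ only in the estimator, so this is exact.

The inner selection metric is **balanced accuracy** by default, with plain
accuracy and AUC as options. Balanced accuracy is the proper-accuracy
analogue of the 1/(2·fraction) weighted loss: measured on the default
synthetic cohort, plain accuracy always prefers the fully shrunk
majority-class logistic model (accuracy 0.784 vs 0.657 for models with
signal, pooled AUC 0.500 vs 0.717), which would zero every coefficient and
make both tuning and feature-selection stability vacuous on any cohort
this imbalanced.

The sparse logistic model is L1-penalized class-weighted maximum
likelihood (liblinear coordinate descent, tolerance 1e-6); the default C
grid is 10 points log-spaced 10⁻³…10³. Grid ties resolve to the first
declared candidate — determinism over optimism. Tree learners delegate to
the standard scikit-learn implementations (bagging averages bootstrap-
resampled tree probabilities); the bespoke contract here is the balancing,
nesting, pooling and stability accounting around them. One global seed
fans out to per-fold seeds through a `SeedSequence` keyed by
(fold, candidate) indices, keeping every derived seed below 2³¹.

Pooled predictions yield the ROC at every distinct predicted probability;
AUC is the trapezoid area, which equals Mann–Whitney concordance with ties
at ½ (enforced against an O(n²) oracle in the tests). The Brier score is
the mean squared probability error. Feature stability counts, per feature,
the outer folds whose refit kept a nonzero coefficient.

## Composite risk score

The deployment model is tuned by the same inner search on the full data,
refitted on all rows, and back-transformed from the standardized scale to
raw units: b_raw = b_std/sd, b₀_raw = b₀_std − Σ b_std·mean/sd. The
back-transformation is checked by requiring raw- and standardized-scale
probabilities to agree to 1e-10 on every sample. Default deployment
predictors are antenatal fasting glucose and HbA1c — the two features the
stability analysis singles out; full-feature fitting is a config option.

Operating points at predetermined target sensitivities (60/70/75/80/90%)
pick, per target, the largest cut-point whose achieved sensitivity meets
the target (candidates are the observed positive scores; classification is
score ≥ c, ties positive).

## K-L divergence cut-point framework

All divergences are in nats. The scan grid is 1000 points, 0.000–0.999
inclusive at 0.001 spacing (a half-open reading of "0 to 1 in 1000
steps"); argmax ties break toward the smaller cut-point. The `ta` column
is the integer-rounded percent of scores strictly below c.

Any probability entering a logarithm is clamped to [1e-12, 1−1e-12].
Rows where sensitivity or specificity hits exactly 0 or 1 are flagged
`degenerate`; their divergences are large but finite. A practical
consequence worth knowing: when the score distributions overlap, the
unconstrained rule-out maximizer D(g₂‖g₁) genuinely diverges as g₁ → 1
with g₂ > 0, so the selected c_out can land in the flagged degenerate
region (sensitivity exactly 1). The selection is reported as defined —
maximum over the scanned grid — and the `degenerate` column is the
intended filter for users who want the best non-degenerate operating
point instead.

Information graphs: I₊(x) and I₋(x) are implemented as the relative
entropy of the posterior disease distribution (given a positive/negative
result) from the prior at pre-test probability x. This normalization makes
the decomposition I_E(x) = Pr(T₁)·I₊ + (1−Pr(T₁))·I₋ hold identically,
with I_E the mutual information of the 2×2 (status, result) joint — and
that identity, cross-checked against a direct joint-entropy oracle, is the
acceptance test for the choice.

The Bregman representation computes, for h(p) = p ln p + (1−p) ln(1−p),
the crosswise vertical distances between h and its tangents at p = g₁ and
p = 1−g₂; this equals KL_in + KL_out algebraically and is verified to
1e-10 on an interior lattice.

## Decision curves and power

Net benefit is (TP − FP·p_t/(1−p_t))/N with treat-all and treat-none
comparators; the default threshold grid is 0.01–0.99 at 0.01. N defaults
to the prediction-set size and is overridable (e.g. to express benefit per
member of the full screened cohort rather than the labelled subset).

Cohen's d uses the pooled standard deviation. Sample-size solving uses the
noncentral-t power function (statsmodels' two-sample solver) with unequal
allocation r = n₂/n₁, then rounds each group up independently — with the
observed effect d = 0.681, α = 0.05, power 0.90, r = 0.305 this gives
(99, 31), total 130; the rounded-moments effect size is 0.671, so the
package keeps effect size an explicit input rather than recomputing it
from rounded summaries. Power is verified in tests against a direct
scipy noncentral-t oracle and the solver/power pair is checked for mutual
consistency (power at n₁ ≥ target, power at n₁ − 1 below it).

## Problem sizes and determinism

The test suite exercises the full leave-one-out nesting at the study scale
(n = 394) for the stability property, n = 200 for the permutation-null
band, n = 20 000 for moment convergence and coefficient recovery, and
n = 2 000 for cut-point scan geometry — sizes chosen so each property is
measured where its statistical resolution is adequate. Every stochastic
step derives from one explicit seed; rerunning any pipeline configuration
reproduces byte-identical artifacts, and the run log records config, seeds,
per-fold hyperparameters and artifact digests.

## Known limitations

* MCAR is the only missingness mechanism; real screening loss is
  informative.
* Single-imputation chained equations with OLS conditionals — no
  predictive-mean matching, no between-imputation variance.
* The generator's Gaussian marginals and single pairwise correlation are a
  deliberate simplification; interactions and skew present in real
  glycaemic data are absent.
* Degenerate-region divergences depend on the clamping constant; only
  their flagged/non-flagged status, not their magnitude, should be
  interpreted.
* The tree families are evaluated under stratified 4-fold outer CV, so
  their pooled metrics are not strictly comparable to the leave-one-out
  logistic results.
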