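# postgdm

Antenatal prediction of **postpartum prediabetes** in women diagnosed with
gestational diabetes mellitus (GDM), for biostatisticians and clinical
epidemiologists who want the full analysis pipeline — not just a fitted
model — as tested, seeded, re-runnable code.

Women with GDM face a sharply elevated risk of progressing to type-2
diabetes, and postpartum screening attendance is poor. The idea implemented
here is to stratify follow-up *antenatally*: predict each woman's risk of
postpartum prediabetes from measurements already taken at the antenatal
OGTT, then choose decision thresholds that are explicitly optimised for
ruling the condition in or out.

## What the package computes

**Outcome labelling.** Postpartum glucose tolerance from fasting glucose,
2-h postprandial glucose (mmol/L) and HbA1c (mmol/mol, IFCC), under NICE
(default), WHO or ADA threshold sets; diabetes takes precedence over
prediabetes, all comparisons inclusive (≥).

**Nested cross-validated evaluation.** Outer leave-one-out CV (stratified
k-fold for the tree ensembles) with an inner stratified 4-fold grid search
per outer fold. Chained-equations imputation, z-scoring and the class
weights w_k = 1/(2·fraction_k) are all fitted on each fold's training rows
only. Held-out probabilities are pooled into one prediction per woman;
ROC/AUC, the Brier score and per-fold L1 selected-feature stability are
computed on that pooled set.

**Composite risk score.** The deployment model is a class-weighted
L1-logistic fit whose coefficients are back-transformed to raw units, giving

    P(prediabetes) = 1 / (1 + exp(−(b₀ + b₁·A-FG + b₂·A-HbA1c)))

with the published coefficients (−8.36, 0.58, 0.10) available as
`published_risk_model()`.

**Information-theoretic cut-points.** At cut-point c the dichotomized score
has sensitivity g₁(c) and specificity g₂(c), viewed as Bernoulli response
distributions. The package scans 1000 cut-points and maximizes

    D(g₁‖g₂) = g₁ ln(g₁/(1−g₂)) + (1−g₁) ln((1−g₁)/g₂)   (rule-in)
    D(g₂‖g₁) = (1−g₂) ln((1−g₂)/g₁) + g₂ ln(g₂/(1−g₁))   (rule-out)
    TKL(c)   = D(g₁‖g₂) + D(g₂‖g₁)                        (combined)

yielding the tests T_in, T_out and T_in−out, with odds multipliers
P = e^D, information distinguishability ID = 1 − e^(−D), full per-threshold
metric tables, information graphs (posterior-vs-prior relative entropy
against pre-test probability) and the Bregman-divergence representation of
TKL.

**Decision curves and power.** Net benefit (TP − FP·p_t/(1−p_t))/N against
treat-all/treat-none, and two-sample t-test power (noncentral t) with
Cohen's d and unequal allocation.

**Synthetic cohorts.** A seeded generator reproduces the study's
statistical structure (n = 394, prevalence 23.35%, class-conditional
antenatal/postpartum moments, latent-logistic outcome on fasting glucose
and HbA1c), so every stage is testable end-to-end with no data download.

## Worked example

```python
import postgdm as pg

# published two-variable score on raw antenatal inputs
model = pg.published_risk_model()
for fg, hb in [(4.6, 33.0), (5.4, 38.0), (6.5, 44.0)]:
    print(f"A-FG {fg:.1f} mmol/L, A-HbA1c {hb:.1f} mmol/mol "
          f"-> risk {pg.composite_risk(model, fg, hb):.3f}")

# score a synthetic cohort and inspect the published cut-points
table = pg.generate_cohort(pg.GeneratorSpec(n=394, seed=7))
scores = pg.composite_risk(model, table.data["a_fg"], table.data["a_hba1c"])
preds = pg.AggregatedPredictions.from_arrays(
    scores, table.binary_outcome().astype(int))
print(f"AUC {pg.roc_auc(preds).auc:.3f}")
for c in (0.140, 0.260, 0.381):
    r = pg.threshold_metrics(preds, c)
    print(f"c={c:.3f}: sens {r.g1:.2f} spec {r.g2:.2f} J {r.j:.2f} "
          f"KL_in {r.kl_in:.3f} P_in {r.p_in:.2f} TA {r.ta}%")

n1, n2 = pg.solve_sample_size(pg.PowerSpec(d=0.681, ratio=0.305))
print(f"minimum sample size: {n1} + {n2} = {n1 + n2}")
```

prints

```
A-FG 4.6 mmol/L, A-HbA1c 33.0 mmol/mol -> risk 0.084
A-FG 5.4 mmol/L, A-HbA1c 38.0 mmol/mol -> risk 0.193
A-FG 6.5 mmol/L, A-HbA1c 44.0 mmol/mol -> risk 0.453
AUC 0.673
c=0.140: sens 0.57 spec 0.68 J 0.25 KL_in 0.128 P_in 1.14 TA 61%
c=0.260: sens 0.16 spec 0.95 J 0.11 KL_in 0.083 P_in 1.09 TA 92%
c=0.381: sens 0.02 spec 1.00 J 0.02 KL_in 0.017 P_in 1.02 TA 99%
minimum sample size: 99 + 31 = 130
```

Risk rises monotonically in both antenatal measures; on this synthetic
cohort the published score separates outcomes with AUC ≈ 0.67, and each
cut-point row shows the sensitivity/specificity trade plus the K-L
information a positive result carries (P_in is the factor by which a
positive test multiplies the disease odds; TA is the percent of the cohort
scoring below c). The power solve says 130 women (99 + 31 at the observed
92/302 allocation) suffice to detect the fasting-glucose effect
(d = 0.681) with 90% power at α = 0.05.

The same stages are scriptable from the shell:

```sh
postgdm run --seed 1 --out results/run1          # full pipeline bundle
postgdm simulate --seed 7 --out cohort.csv
postgdm power --d 0.681 --ratio 0.305
```

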