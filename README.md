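# cadscore

Development pipeline for a whole-blood gene-expression classifier of
obstructive coronary artery disease (CAD) in non-diabetic patients.

Circulating blood cells change their transcriptional state with
atherosclerosis: neutrophil-expressed genes shift with CAD in opposite
directions in men and women, while lymphocyte-expressed genes go down in
both sexes.  `cadscore` implements, end to end, the procedure that turns
those observations into a locked diagnostic score: microarray/RT-PCR
discovery statistics, RT-PCR panel selection, meta-gene/ratio-term
construction, penalized model fitting, cross-validated evaluation, and the
final locked 23-gene / 6-term score.  A synthetic-cohort generator with
the same statistical structure (latent cell-type fractions, sex-antagonistic
CAD shifts, age/sex-dependent case probability, triplicate PCR wells
aggregated by median) makes every stage testable without any real data.

It is intended for statisticians and computational biologists who want a
reproducible, fully tested reference implementation of this class of
blood-transcriptomic classifier development — not for clinical use; the
packaged default score coefficients are fitted to synthetic data.

## The model

Genes are grouped by expression correlation; each cluster is summarised by a
*meta-gene* (weighted mean of 1–4 log₂-scale genes, equal weights by
default).  For highly correlated meta-gene pairs with opposite disease
regulation, a *ratio term* is the difference on the log scale,

&nbsp;&nbsp;&nbsp;&nbsp;Tₖ = meta-gene(numerator) − meta-gene(denominator),

which cancels shared cell-count variation.  The classifier is a penalized
logistic regression of case:control status:

&nbsp;&nbsp;&nbsp;&nbsp;logit P(CAD) = β₀ + Σₖ wₖ·Tₖ (+ sex-interaction copies)
+ βₛ·I(male) + βₘ·age·I(male) + β_f·max(age−60, 0)·I(female)

Women below the 60-year knot contribute no age effect.  Terms are selected
by L1 (lasso) logistic regression with sex-by-term interactions allowed and
the sex/age columns unpenalized, then re-fit with an L2 (ridge) penalty;
both shrinkage parameters come from stratified 10-fold cross-validated
deviance (the lasso uses the one-standard-error parsimony rule).
Performance is estimated by leave-one-out cross-validation and ROC AUC with
a DeLong confidence interval.

The locked structure comprises 23 genes in 6 terms (20 informative + 3
normalization genes: RPL28, HNRNPF, TFCP2).  Term 2 is normalized to RPL28
in men and to AQP9+NCF4 in women; Term 6 (TSPAN16) applies to men only.
Expression inputs are log₂ intensities or −ΔCt-like values: **higher value
= more transcript**.

## Worked example

```python
from cadscore import CADClassifier, locked

structure = locked.locked_term_definitions()
matrix, samples, _, _ = locked.locked_reference_cohort(n_samples=640, seed=11)
tv = locked.term_values(matrix, samples, structure).fillna(0.0)
clf = CADClassifier(tv, samples,
                    term_sex={t: structure.term_sex(t) for t in structure.term_map})
res = clf.fit(seed=11)
print(res.summary())
cv = res.loocv(seed=11)
print(f"LOOCV AUC = {cv.auc:.3f} (95% CI {cv.ci_low:.3f}-{cv.ci_high:.3f})")
```

prints

```
CAD gene-expression classifier (lasso selection + ridge fit)
==============================================================
n = 640 (248 cases / 392 controls)
lasso lambda = 0.0161321; terms selected: T1, T3, T4, T5, T6, T2
ridge lambda = 0.00172979; age knot = 60 y; seed = 11
--------------------------------------------------------------
parameter                       coef          se
intercept                    -0.1069          --
T1                           -1.3024      0.2288
T3                           -0.3100      0.0864
T4                            0.1922      0.0871
T5                            0.1855      0.1346
T6                            0.1094      0.1121
T1:male                       2.4236      0.2781
T2:male                       0.2922      0.0868
T5:male                       0.1411      0.1745
sex_male                     -9.0921      1.0737
age_male                      0.0828      0.0124
age_female_hinge              0.1012      0.0220
--------------------------------------------------------------
in-sample AUC = 0.858 (95% CI 0.828-0.887; optimistic, see loocv())
LOOCV AUC = 0.844 (95% CI 0.813-0.875)
```

Reading the output: all six locked terms are re-selected from the synthetic
cohort.  The large positive `T1:male` against the negative female main
effect of `T1` is the sex-antagonistic neutrophil signal this world plants
(up-regulated with CAD in men, down in women); `sex_male` re-calibrates the
male intercept against those term shifts plus the male age slope.  The
leave-one-out AUC of 0.844 is the honest performance estimate; the
in-sample 0.858 is optimistic because the same samples chose the terms.

A command-line interface mirrors the library
(`cadscore simulate | qc | discover | cluster | select-panel | fit | loocv |
score | report`); each run logs its seed, resolved configuration and input
digests to stderr.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch on a freshly generated synthetic
development cohort: PCR triplicate measurement, sample QC, unpaired /
sex-age-adjusted / matched-pair conditional association, correlation
clustering, normalization-gene screening, lasso+ridge fitting, LOOCV, and
locked-score batch scoring, logging a stage-by-stage summary to stderr and
writing the (empty) target report to `--out`.
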