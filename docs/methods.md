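# Methods

This note records the statistical models, defaults, and design choices
behind `cadscore`, and what the synthetic-data tests do and do not
establish.

## 1. Synthetic cohort generator (`cadscore.simulate`)

The generator emulates the statistical structure of a blood-transcriptomic
case:control study of obstructive CAD:

* **Phenotype.** Sex is Bernoulli(male_fraction); age is Normal(age_mean,
  age_sd) truncated to [25, 90].  Case status follows a logistic model,
  logit p = β₀ + log(OR_age)/10·(age − age_mean) + log(OR_male)·I(male),
  with β₀ solved by root-finding so the realised mean case probability
  equals `case_fraction`.  Defaults (n = 640, case fraction 0.36, 58% male,
  age 60 ± 12, OR 2.0 per decade, OR 2.5 for male sex) mirror a typical
  angiography-referral development cohort.
* **Expression.** Genes belong to clusters driven by latent cell-type
  activities (neutrophil, T/B lymphocyte, NK, eosinophil; standard-normal
  scalars per sample): x₉ₛ = b₉ + loading·activity + CAD shift + ε,
  ε ~ N(0, noise_sd²), noise_sd default 1.0 log₂ unit.  Blood counts are
  affine in the same activities (neutrophils 4.0 ± 1.3, lymphocytes
  1.9 ± 0.65 ×10³/µL), so count–expression correlations arise mechanically
  (|r| ≈ loading/√(loading²+noise²); ≈ 0.57 at the default loading 0.7).
* **Baselines** b₉ ~ Uniform(6, 12) come from a *fixed* random stream
  independent of the cohort seed: they are properties of the assay panel,
  not of a cohort draw.  This is what makes locked coefficients transport
  between cohorts — during development we observed that per-seed baselines
  silently destroy cross-sex score calibration on fresh cohorts.
* **CAD shifts** are per-cluster log₂ offsets in cases with four sex modes:
  `both`, `antagonistic` (+shift in men, −shift in women; the neutrophil
  pattern), `male_only`, `female_only`.  In diabetics the shift is
  multiplied by `diabetic_effect_multiplier` (0 abolishes the association —
  the simplest mechanism producing disjoint significant-gene sets in
  diabetic and non-diabetic subsets).
* **RT-PCR measurement** draws three replicate wells with Gaussian noise
  (default 0.2 Ct) and contaminates each independently with probability
  `outlier_rate` by a fixed +10-unit shift, then reports the median.  The
  fixed shift makes the median-vs-mean robustness property sharp.
* **Pair matching** is an age-sorted sweep within sex: each case (ascending
  age) takes the youngest unused control within the tolerance.  For
  interval compatibility this greedy is cardinality-optimal, and it matches
  the exact maximum-matching oracle on every tested instance; a
  nearest-age-first greedy (the obvious alternative) loses up to ~10% of
  pairs and was rejected.
* **Generative oracle.** Because the class-conditional expression
  distribution is Gaussian with shared covariance Σ = noise²·I +
  Σ_celltype v vᵀ, the Bayes-optimal score is available in closed form:
  per sex, w = Σ⁻¹δ applied to (x − μ₀ − δ/2), plus the logit of the
  age/sex case probability.  `bayes_auc` Monte-Carlo-estimates its AUC on a
  fresh 20,000-sample draw.  A linear `projection` restricts the oracle to
  the observable a classifier actually uses (ratio-term space): the
  unprojected gene-space bound is unreachable for ratio-term models by
  construction, since a ratio term adds denominator noise.

**What a green test establishes.** Correct recovery behaviour under a
correctly specified, Gaussian, single-batch world.  The generator does
*not* emulate probe-level microarray artefacts, batch effects, platform
differences, non-Gaussian tails, or real-data marginals; passing tests say
nothing about robustness to those.

## 2. Discovery statistics (`cadscore.discovery`)

* **Normalization**: per sample, scale so the two-sided trimmed mean equals
  100 (trim 0.02 per tail by default; the study protocol does not print its
  trim), then log₂(x + 1).  The +1 offset keeps zeros finite, is monotone,
  and preserves invariance to per-sample rescaling.
* **QC**: percent present (> 1.0 on the matrix scale), median pairwise
  Pearson r, and median intensity within ±3 robust SDs (1.4826·MAD) of the
  cohort median.  Defaults 60% / 0.6 / 3 MAD are conventional; the original
  exclusion cutoffs are unrecoverable, so all are configurable.
* **Per-gene association**: logistic regression of status on expression
  (optionally + sex + age) via statsmodels, Wald p.  Constant genes are
  flagged `degenerate` (β = 0, p = 1).  Complete separation is flagged, β
  is capped at ±15 with the iteration cap at 25, and the p-value falls back
  to the efficient-score (Rao) test, which stays well-defined.  The
  `robust` variant is an IRLS fit with Huber weights min(1, 1.345/|rᵢ|) on
  deviance residuals, re-evaluated each iteration — a standard resistant
  GLM choice; plain ML is the default.
* **Matched pairs**: the 1:1 conditional likelihood L(β) = Π
  [1+exp(−β·dᵢ)]⁻¹ on within-pair differences dᵢ, maximised by Newton
  iteration; a score test at β = 0 (z = Σd/√Σd²) is reported alongside the
  Wald p.  This is algebraically identical to intercept-free logistic
  regression on the differences, which the tests exploit as an independent
  route.
* **Multiplicity** is Benjamini–Hochberg step-up; **enrichment** is the
  upper-tail hypergeometric test against user-supplied gene sets (no
  ontology database is shipped); **clinical factors** use univariate /
  multivariate logistic Wald tests for continuous factors and Pearson
  chi-square without continuity correction for categorical ones (the
  uncorrected statistic reproduces the published chest-pain p ≈ 4e-4 on the
  printed 4×2 table).

## 3. Panel selection (`cadscore.panel`)

Gene clustering is agglomerative with distance 1 − Pearson r and average
linkage, cut at height 1 − cutoff; average linkage is the unstated-but-
predictable choice for a correlation-cutoff reading, and correlations pool
cases and controls.  Cell-type tags come from count correlations
(neutrophil count → `neutrophil`; total lymphocyte count → the
lineage-level `lymphocyte` tag, since a total count cannot honestly name a
subset) and from user-supplied marker genes.  Normalization candidates must
sit in the low-variance quantile, the moderate-to-high expression band, and
show no screen association (Pearson/point-biserial, p ≥ α) with status,
sex, age, or either count.  Panel selection is greedy: best-p gene per
significant cluster first, then priority flags, then p, with a documented
lexicographic tie-break.  The published 113-gene panel itself was a
judgment call and is shipped as a packaged reference table rather than
re-derived.

## 4. Classifier fitting (`cadscore.model`, `cadscore.glmnet`)

The penalized logistic engine is written in-house because per-column
penalty factors (sex/age unpenalized) are not available in scikit-learn.
It follows the glmnet algorithm: IRLS outer loop, covariance-update cyclic
coordinate descent with active-set sweeps inside, warm starts along a
100-point log-spaced λ grid from the data-driven λ_max down to λ_max/10⁴,
and internal column standardization (the L1 penalty acts on the
standardized scale; coefficients are returned on the original scale).  Two
pragmatic guards keep the separated small-λ tail cheap: iteration caps and
a glmnet-style early exit once 99% of the null deviance is explained — CV
never chooses that regime.  Fits agree with statsmodels'
`Logit.fit_regularized(method="l1")` to ~1e-6 on standardized fixtures and
with unpenalized ML at λ = 0 to 1e-6.

**λ rules.**  Both penalties use stratified 10-fold CV deviance.  The ridge
λ takes the deviance minimum.  The lasso λ defaults to the
one-standard-error rule: at the benchmark recovery world (n = 600, 15
terms, 6 planted at 0.5 log₂ units, unit noise) the min-deviance rule
selected a median of ~4–5 spurious terms and met the ≥5 planted / ≤3
spurious recovery requirement in only 7/20 seeds, while the 1-SE rule met
it in 20/20 with essentially no loss of planted terms.  `rule="min"`
remains available.

LOOCV refits the ridge coefficients for each held-out sample with the term
set *and* λ fixed from the full-data fit — matching the development
procedure, which did not re-select terms per iteration, and keeping the
estimate deterministic; this retains the selection's optimism, which the
nested mode (`reselect=True`, full lasso + ridge CV inside every fold)
quantifies.  AUC is the Mann–Whitney rank statistic (ties half-credit) with
a DeLong CI, replaced by a seeded 2,000-rep percentile bootstrap below 30
samples per class.

## 5. The locked score (`cadscore.locked`)

The six-term registry (validated at load: 23 unique genes, 20 informative,
3 normalization, 6 terms) is parsed from the packaged panel table.  The
score is intercept + Σ wₜ·Tₜ + sex and age contributions as in the README;
Term 2 resolves its denominator by sex, Term 6 contributes only for men,
and an optional monotone affine transform (a > 0) maps the raw regression
value to a reporting scale (identity by default; the original transform is
not public).  AF289562/A_24_P128361 and AF161365/TSPAN16 are registered
under both accession and symbol, resolved by exact match.

The packaged default coefficients are a ridge fit on the packaged synthetic
reference cohort (n = 640, seed 17; `scripts/make_reference_coefficients.py`
regenerates them) and are explicitly non-clinical.  In the reference world
the per-component CAD shifts are ±0.35–0.45 log₂ units — antagonistic for
neutrophil components, sex-independent down for lymphocyte/NK components,
male-only for TSPAN16 — values chosen once for test power (the study
reports directions, not effect sizes) and not revisited.

## 6. Numerical conventions and edge cases

* Floats serialise at 9 significant digits; writers are byte-stable.
* Linear predictors are clipped at |η| ≤ 30; IRLS weights floored at 1e-5.
* Logistic iteration caps: 25 (per-gene fits), with |β| ≤ 15 reported under
  separation and score-test p-values.
* Ties in panel selection and AUC break lexicographically / with half
  credit, respectively; CV folds are stratified with a stored seed.
* Sample sheets normalise status/sex tokens case-insensitively; records
  missing age are kept but flagged and excluded (with a warning) from
  age-requiring stages.

## 7. Known limitations

* The development and validation cohorts of the original study are not
  publicly available at RT-PCR level; published headline AUCs are therefore
  out of reach, and all quantitative tests run against synthetic worlds.
* The robust logistic variant is a down-weighting heuristic, not an exact
  reproduction of the study's (uncited, unspecified) robust method.
* Enrichment is generic: no GO database content ships with the package.
* The `lymphocyte` count tag cannot distinguish T/B/NK contributions;
  marker-based evidence is needed for that.
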