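"""Meta-gene terms and the CAD classifier model.

The modelling objects follow the statsmodels convention: a
:class:`CADClassifier` is built from data (term definitions + expression +
phenotypes) and its :meth:`~CADClassifier.fit` returns a
:class:`CADClassifierResults` carrying the estimates, approximate standard
errors, diagnostics, a ``summary()`` table, prediction, and leave-one-out
cross-validation.

Model structure
---------------
Each *meta-gene* is a weighted mean of 1-4 log-scale genes; a *ratio term*
is the difference of two meta-genes on the log scale (a ratio on the linear
scale).  The design contains, in deterministic order: one column per term
(sex-restricted terms are zeroed in the other sex), sex-interaction copies
of the unrestricted terms, a male indicator, a male linear age column
``age * I(male)``, and a female hinge column ``max(age - knot, 0) *
I(female)`` (women below the knot contribute no age effect).  Terms are
selected by an L1-penalized (lasso) logistic fit with the sex/age columns
unpenalized, then refit with an L2 (ridge) penalty; both shrinkage
parameters are chosen by stratified 10-fold cross-validated deviance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import glmnet
from .containers import (ConfigurationError, DataError, ExpressionMatrix,
                         case_indicator)

SEX_APPLICABILITY = ("both", "male_only", "female_only")
UNPENALIZED_COLUMNS = ("sex_male", "age_male", "age_female_hinge")


# ---------------------------------------------------------------------------
# meta-genes and terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaGene:
    """A set of 1-4 genes summarised as a weighted mean of log expression."""

    id: str
    genes: tuple
    weights: tuple = None
    sign: int = 1

    def __post_init__(self):
        genes = tuple(self.genes)
        object.__setattr__(self, "genes", genes)
        if not 1 <= len(genes) <= 4:
            raise ConfigurationError(
                f"meta-gene {self.id!r} must contain 1-4 genes, got {len(genes)}")
        if len(set(genes)) != len(genes):
            raise ConfigurationError(f"meta-gene {self.id!r} has duplicate genes")
        w = self.weights
        if w is None:
            w = tuple(1.0 / len(genes) for _ in genes)
        else:
            w = tuple(float(x) for x in w)
            if len(w) != len(genes):
                raise ConfigurationError("weights length != gene count")
            if abs(sum(w) - 1.0) > 1e-9:
                raise ConfigurationError("meta-gene weights must sum to 1")
        object.__setattr__(self, "weights", w)
        if self.sign not in (-1, 1):
            raise ConfigurationError("sign must be +1 or -1")


@dataclass(frozen=True)
class TermDefinition:
    """Ratio term: numerator minus denominator meta-gene on the log scale."""

    id: str
    numerator: MetaGene
    denominator: MetaGene
    sex: str = "both"

    def __post_init__(self):
        if self.sex not in SEX_APPLICABILITY:
            raise ConfigurationError(f"unknown sex applicability {self.sex!r}")
        if (self.numerator.id == self.denominator.id
                and self.numerator.genes == self.denominator.genes):
            raise ConfigurationError(
                f"term {self.id!r}: numerator equals denominator")

    @property
    def genes(self) -> tuple:
        return tuple(dict.fromkeys(self.numerator.genes + self.denominator.genes))


def build_metagene(matrix: ExpressionMatrix, metagene: MetaGene) -> pd.Series:
    """Per-sample meta-gene value (weighted mean of log-scale expression)."""
    missing = [g for g in metagene.genes if g not in matrix.genes]
    if missing:
        raise DataError(f"meta-gene {metagene.id!r}: missing genes {missing}")
    sub = matrix.data.loc[list(metagene.genes)]
    w = np.asarray(metagene.weights)
    return pd.Series(metagene.sign * (w @ sub.to_numpy()),
                     index=matrix.samples, name=metagene.id)


def build_term(matrix: ExpressionMatrix, term: TermDefinition) -> pd.Series:
    """Per-sample ratio-term value (numerator minus denominator)."""
    num = build_metagene(matrix, term.numerator)
    den = build_metagene(matrix, term.denominator)
    out = num - den
    out.name = term.id
    return out


def build_term_table(matrix: ExpressionMatrix, terms) -> pd.DataFrame:
    return pd.DataFrame({t.id: build_term(matrix, t) for t in terms})


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def make_design(term_values: pd.DataFrame, samples: pd.DataFrame,
                knot: float = 60.0, sex_interactions: bool = True,
                term_sex: dict | None = None) -> pd.DataFrame:
    """Assemble the classifier design matrix.

    Columns, in order: one per term (sex-restricted terms zeroed for the
    other sex), then ``<term>:male`` interaction copies for unrestricted
    terms (if ``sex_interactions``), then ``sex_male``, ``age_male`` and
    ``age_female_hinge``.  No intercept column (fitters add their own).
    """
    samples = samples.loc[term_values.index]
    if samples["age"].isna().any() or samples.get("age_missing", pd.Series(False, index=samples.index)).any():
        bad = samples.index[samples["age"].isna() | samples["age_missing"]].tolist()
        raise DataError(f"missing age for samples {bad}")
    male = (samples["sex"] == "M").astype(float)
    term_sex = term_sex or {}
    cols = {}
    for t in term_values.columns:
        applicability = term_sex.get(t, "both")
        v = term_values[t].astype(float)
        if applicability == "male_only":
            cols[t] = v * male
        elif applicability == "female_only":
            cols[t] = v * (1.0 - male)
        else:
            cols[t] = v
    if sex_interactions:
        for t in term_values.columns:
            if term_sex.get(t, "both") == "both":
                cols[f"{t}:male"] = term_values[t].astype(float) * male
    cols["sex_male"] = male
    cols["age_male"] = samples["age"].astype(float) * male
    cols["age_female_hinge"] = np.maximum(samples["age"].astype(float) - knot, 0.0) * (1.0 - male)
    return pd.DataFrame(cols, index=term_values.index)


def penalty_factor(design: pd.DataFrame) -> np.ndarray:
    """1 for term columns, 0 for the sex/age covariates (never shrunk)."""
    return np.array([0.0 if c in UNPENALIZED_COLUMNS else 1.0
                     for c in design.columns])


# ---------------------------------------------------------------------------
# selection and fitting
# ---------------------------------------------------------------------------

@dataclass
class LassoSelection:
    """Outcome of the lasso variable-selection step."""

    selected_columns: list
    selected_terms: list
    lambda_best: float
    coefficients: pd.Series
    cv_curve: object


def lasso_select(design: pd.DataFrame, outcome, n_folds: int = 10,
                 seed: int = 0, n_lambda: int = 100,
                 rule: str = "1se") -> LassoSelection:
    """L1 term selection with cross-validated lambda.

    Lambda defaults to the one-standard-error rule on the CV deviance curve
    (``rule="min"`` gives the raw deviance minimum, which over-selects
    noise terms).  A term counts as selected when its main column or its
    sex-interaction copy has a nonzero coefficient; the sex/age columns are
    unpenalized and always retained.
    """
    y = np.asarray(outcome, float)
    pf = penalty_factor(design)
    b0, beta, curve = glmnet.cv_lasso(design.to_numpy(), y, penalty_factor=pf,
                                      n_folds=n_folds, seed=seed,
                                      n_lambda=n_lambda, rule=rule)
    coefs = pd.Series(beta, index=design.columns)
    selected_cols = [c for c, b in coefs.items()
                     if b != 0 and c not in UNPENALIZED_COLUMNS]
    terms = []
    for c in selected_cols:
        t = c.split(":male")[0]
        if t not in terms:
            terms.append(t)
    return LassoSelection(selected_columns=selected_cols, selected_terms=terms,
                          lambda_best=curve.lambda_best, coefficients=coefs,
                          cv_curve=curve)


@dataclass
class ClassifierModel:
    """A fitted, self-contained scoring model.

    ``coefficients`` maps design-column names (terms, interactions, sex and
    age columns) to weights; the score of a sample is the logistic linear
    predictor ``intercept + sum coef * column``.
    """

    intercept: float
    coefficients: dict
    knot: float = 60.0
    lambda_lasso: float | None = None
    lambda_ridge: float | None = None
    seed: int | None = None
    term_sex: dict = field(default_factory=dict)

    @property
    def sex_coefficient(self) -> float:
        return self.coefficients.get("sex_male", 0.0)

    @property
    def male_age_slope(self) -> float:
        return self.coefficients.get("age_male", 0.0)

    @property
    def female_age_hinge_slope(self) -> float:
        return self.coefficients.get("age_female_hinge", 0.0)

    def score(self, design: pd.DataFrame) -> pd.Series:
        s = pd.Series(self.intercept, index=design.index, dtype=float)
        for col, w in self.coefficients.items():
            if col not in design.columns:
                raise DataError(f"design lacks column {col!r}")
            s = s + w * design[col].astype(float)
        if not np.isfinite(s).all():
            raise DataError("non-finite score")
        return s


def ridge_fit(design: pd.DataFrame, outcome, n_folds: int = 10, seed: int = 0,
              lam: float | None = None, knot: float = 60.0,
              term_sex: dict | None = None):
    """Ridge refit of the selected design; lambda by 10-fold CV when not given.

    Returns (ClassifierModel, standard-error Series from the inverse
    penalized Hessian, CVCurve-or-None).
    """
    y = np.asarray(outcome, float)
    X = design.to_numpy()
    pf = penalty_factor(design)
    curve = None
    if lam is None:
        b0, beta, hess, curve = glmnet.cv_ridge(X, y, penalty_factor=pf,
                                                n_folds=n_folds, seed=seed)
        lam = curve.lambda_best
    else:
        b0, beta, hess = glmnet.ridge_logistic(X, y, lam, penalty_factor=pf)
    cov = np.linalg.inv(hess)
    se = pd.Series(np.sqrt(np.diag(cov))[1:], index=design.columns)
    model = ClassifierModel(intercept=float(b0),
                            coefficients=dict(zip(design.columns, beta)),
                            knot=knot, lambda_ridge=float(lam), seed=seed,
                            term_sex=dict(term_sex or {}))
    return model, se, curve


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels, ci: bool = True, seed: int = 0,
            n_boot: int = 2000):
    """Rank-statistic AUC with a confidence interval.

    AUC is the Mann-Whitney statistic (ties get half credit).  The 95% CI
    uses the DeLong asymptotic variance; for fewer than 30 samples in either
    class a seeded percentile bootstrap (``n_boot`` reps) is used instead.
    Returns (auc, (lo, hi)) or just auc when ``ci=False``.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("AUC needs both classes")
    auc = _auc_value(pos, neg)
    if not ci:
        return auc
    if min(len(pos), len(neg)) < 30:
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            reps[b] = _auc_value(rng.choice(pos, len(pos)),
                                 rng.choice(neg, len(neg)))
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        v10, v01 = _delong_placements(pos, neg)
        var = (np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg))
        half = 1.959963984540054 * np.sqrt(max(var, 0.0))
        lo, hi = auc - half, auc + half
    lo = min(max(lo, 0.0), auc)
    hi = max(min(hi, 1.0), auc)
    return auc, (float(lo), float(hi))


def _auc_value(pos, neg):
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n1, n0 = len(pos), len(neg)
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_placements(pos, neg):
    # placement values: per case, fraction of controls it beats (ties=1/2)
    all_scores = np.concatenate([pos, neg])
    n1, n0 = len(pos), len(neg)
    rk = stats.rankdata(all_scores)
    rk_pos = stats.rankdata(pos)
    rk_neg = stats.rankdata(neg)
    v10 = (rk[:n1] - rk_pos) / n0
    v01 = 1.0 - (rk[n1:] - rk_neg) / n1
    return v10, v01


# ---------------------------------------------------------------------------
# the Model / Results pair
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Out-of-fold scores and their AUC."""

    scores: pd.Series
    auc: float
    ci_low: float
    ci_high: float
    scheme: str


class CADClassifier:
    """CAD classifier model: ratio terms + sex-specific age covariates.

    Parameters
    ----------
    term_values
        samples x terms DataFrame of precomputed ratio-term values.
    samples
        validated phenotype table (needs status, sex, age).
    term_sex
        optional mapping term id -> {"both", "male_only", "female_only"}.
    knot
        female age-hinge knot in years (default 60: women younger than the
        knot contribute no age effect).
    """

    def __init__(self, term_values: pd.DataFrame, samples: pd.DataFrame,
                 term_sex: dict | None = None, knot: float = 60.0):
        if not term_values.index.equals(samples.index):
            samples = samples.loc[term_values.index]
        self.term_values = term_values
        self.samples = samples
        self.term_sex = dict(term_sex or {})
        self.knot = float(knot)
        self.endog = case_indicator(samples)
        if len(np.unique(self.endog)) < 2:
            raise DataError("need both cases and controls")
        self.exog = make_design(term_values, samples, knot=knot,
                                term_sex=self.term_sex)

    @classmethod
    def from_cohort(cls, matrix: ExpressionMatrix, samples: pd.DataFrame,
                    terms, knot: float = 60.0) -> "CADClassifier":
        """Build the model from an expression matrix and term definitions."""
        matrix = matrix.align_samples(samples)
        tv = build_term_table(matrix, terms)
        term_sex = {t.id: t.sex for t in terms}
        obj = cls(tv, samples, term_sex=term_sex, knot=knot)
        obj.terms = list(terms)
        return obj

    def fit(self, seed: int = 0, n_folds: int = 10,
            lambda_lasso: float | None = None,
            lambda_ridge: float | None = None,
            select: bool = True, n_lambda: int = 100) -> "CADClassifierResults":
        """Lasso term selection followed by a ridge refit.

        With ``select=False`` every term enters the ridge fit.  Shrinkage
        parameters default to 10-fold cross-validated deviance minima.
        """
        if select:
            if lambda_lasso is not None:
                pf = penalty_factor(self.exog)
                _, beta = None, None
                ints, betas = glmnet.lasso_logistic_path(
                    self.exog.to_numpy(), self.endog,
                    np.array([lambda_lasso]), penalty_factor=pf)
                coefs = pd.Series(betas[0], index=self.exog.columns)
                sel_cols = [c for c, b in coefs.items()
                            if b != 0 and c not in UNPENALIZED_COLUMNS]
                terms = list(dict.fromkeys(c.split(":male")[0] for c in sel_cols))
                selection = LassoSelection(sel_cols, terms, lambda_lasso,
                                           coefs, None)
            else:
                selection = lasso_select(self.exog, self.endog,
                                         n_folds=n_folds, seed=seed,
                                         n_lambda=n_lambda)
            keep = selection.selected_columns + list(UNPENALIZED_COLUMNS)
        else:
            selection = None
            keep = list(self.exog.columns)
        design_sel = self.exog[[c for c in self.exog.columns if c in keep]]
        model, se, curve = ridge_fit(design_sel, self.endog, n_folds=n_folds,
                                     seed=seed, lam=lambda_ridge,
                                     knot=self.knot, term_sex=self.term_sex)
        model.lambda_lasso = selection.lambda_best if selection else None
        model.seed = seed
        return CADClassifierResults(self, model, se, selection,
                                    ridge_cv=curve, seed=seed,
                                    n_folds=n_folds, n_lambda=n_lambda)


class CADClassifierResults:
    """Fitted classifier: estimates, uncertainties, diagnostics, CV."""

    def __init__(self, model_obj: CADClassifier, fitted: ClassifierModel,
                 bse: pd.Series, selection: LassoSelection | None,
                 ridge_cv=None, seed: int = 0, n_folds: int = 10,
                 n_lambda: int = 100):
        self.model = model_obj
        self.fitted = fitted
        self.selection = selection
        self.ridge_cv = ridge_cv
        self.seed = seed
        self.n_folds = n_folds
        self.n_lambda = n_lambda
        self.params = pd.Series({"intercept": fitted.intercept,
                                 **fitted.coefficients})
        self.bse = pd.concat([pd.Series({"intercept": np.nan}), bse])
        self.fittedvalues = fitted.score(
            self.model.exog[[c for c in self.model.exog.columns
                             if c in fitted.coefficients]])

    # -- prediction -------------------------------------------------------
    def predict(self, term_values: pd.DataFrame | None = None,
                samples: pd.DataFrame | None = None) -> pd.Series:
        """Real-valued score (logistic linear predictor); in-sample when no

        new data are given."""
        if term_values is None:
            design = self.model.exog
        else:
            design = make_design(term_values, samples, knot=self.model.knot,
                                 term_sex=self.model.term_sex)
        design = design[[c for c in design.columns
                         if c in self.fitted.coefficients]]
        return self.fitted.score(design)

    def auc(self, ci: bool = True):
        """In-sample (optimistic) AUC of the fitted scores."""
        return roc_auc(self.fittedvalues, self.model.endog, ci=ci,
                       seed=self.seed)

    # -- cross-validation -------------------------------------------------
    def loocv(self, reselect: bool = False, seed: int | None = None) -> CVResult:
        """Leave-one-out CV of the fitted structure.

        Default mode refits only the ridge coefficients per left-out sample,
        keeping the selected terms and lambda fixed (the selection is *not*
        repeated per iteration, so the estimate retains the selection's
        optimism).  ``reselect=True`` runs the full nested procedure
        (lasso CV + ridge CV inside every fold).
        """
        seed = self.seed if seed is None else seed
        y = self.model.endog
        n = len(y)
        if n < 20:
            raise DataError("LOOCV needs n >= 20")
        full_design = self.model.exog
        keep_cols = [c for c in full_design.columns
                     if c in self.fitted.coefficients]
        scores = np.empty(n)
        for i in range(n):
            tr = np.ones(n, bool)
            tr[i] = False
            if reselect:
                sel = lasso_select(full_design.iloc[tr], y[tr],
                                   n_folds=self.n_folds, seed=seed,
                                   n_lambda=self.n_lambda)
                cols = [c for c in full_design.columns
                        if c in sel.selected_columns + list(UNPENALIZED_COLUMNS)]
                m, _, _ = ridge_fit(full_design.iloc[tr][cols], y[tr],
                                    n_folds=self.n_folds, seed=seed,
                                    knot=self.model.knot)
            else:
                cols = keep_cols
                m, _, _ = ridge_fit(full_design.iloc[tr][cols], y[tr],
                                    lam=self.fitted.lambda_ridge,
                                    knot=self.model.knot)
            scores[i] = m.score(full_design.iloc[[i]][cols]).iloc[0]
        s = pd.Series(scores, index=full_design.index)
        auc, (lo, hi) = roc_auc(s, y, seed=seed)
        return CVResult(scores=s, auc=auc, ci_low=lo, ci_high=hi,
                        scheme="loocv-nested" if reselect else "loocv")

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        lines = ["CAD gene-expression classifier (lasso selection + ridge fit)",
                 "=" * 62]
        n1 = int(self.model.endog.sum())
        lines.append(f"n = {len(self.model.endog)} "
                     f"({n1} cases / {len(self.model.endog) - n1} controls)")
        if self.selection is not None:
            lines.append(f"lasso lambda = {self.fitted.lambda_lasso:.6g}; "
                         f"terms selected: {', '.join(self.selection.selected_terms) or 'none'}")
        lines.append(f"ridge lambda = {self.fitted.lambda_ridge:.6g}; "
                     f"age knot = {self.fitted.knot:g} y; seed = {self.seed}")
        lines.append("-" * 62)
        lines.append(f"{'parameter':<24}{'coef':>12}{'se':>12}")
        for name, value in self.params.items():
            se = self.bse.get(name, np.nan)
            se_s = f"{se:>12.4f}" if np.isfinite(se) else f"{'--':>12}"
            lines.append(f"{name:<24}{value:>12.4f}{se_s}")
        auc, (lo, hi) = self.auc()
        lines.append("-" * 62)
        lines.append(f"in-sample AUC = {auc:.3f} (95% CI {lo:.3f}-{hi:.3f}; "
                     "optimistic, see loocv())")
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Serialize the locked model (structure + coefficients) as YAML."""
        payload = {
            "intercept": float(self.fitted.intercept),
            "coefficients": {k: float(v)
                             for k, v in self.fitted.coefficients.items()},
            "knot": float(self.fitted.knot),
            "lambda_lasso": self.fitted.lambda_lasso,
            "lambda_ridge": self.fitted.lambda_ridge,
            "seed": self.seed,
            "term_sex": self.fitted.term_sex,
        }
        if getattr(self.model, "terms", None):
            payload["terms"] = [
                {"id": t.id, "sex": t.sex,
                 "numerator": {"id": t.numerator.id,
                               "genes": list(t.numerator.genes),
                               "weights": list(t.numerator.weights)},
                 "denominator": {"id": t.denominator.id,
                                 "genes": list(t.denominator.genes),
                                 "weights": list(t.denominator.weights)}}
                for t in self.model.terms]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def load_model(path) -> ClassifierModel:
    """Load a serialized model back into a scoring object."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return ClassifierModel(intercept=payload["intercept"],
                           coefficients=payload["coefficients"],
                           knot=payload.get("knot", 60.0),
                           lambda_lasso=payload.get("lambda_lasso"),
                           lambda_ridge=payload.get("lambda_ridge"),
                           seed=payload.get("seed"),
                           term_sex=payload.get("term_sex", {}))


def load_terms(path) -> list:
    """Read term definitions from a YAML file (the format ``save`` writes)."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    entries = payload["terms"] if isinstance(payload, dict) else payload
    terms = []
    for e in entries:
        num = MetaGene(e["numerator"]["id"], tuple(e["numerator"]["genes"]),
                       tuple(e["numerator"].get("weights") or ()) or None)
        den = MetaGene(e["denominator"]["id"], tuple(e["denominator"]["genes"]),
                       tuple(e["denominator"].get("weights") or ()) or None)
        terms.append(TermDefinition(e["id"], num, den, e.get("sex", "both")))
    return terms


def loocv_evaluate(matrix: ExpressionMatrix, samples: pd.DataFrame, terms,
                   reselect_terms: bool = False, seed: int = 0,
                   knot: float = 60.0) -> CVResult:
    """Convenience wrapper: build, fit, and LOOCV-evaluate in one call."""
    clf = CADClassifier.from_cohort(matrix, samples, terms, knot=knot)
    res = clf.fit(seed=seed)
    return res.loocv(reselect=reselect_terms, seed=seed)
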