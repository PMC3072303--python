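"""Normalization, QC, per-gene CAD association and related statistics.

Implements the discovery-stage toolkit: per-array trimmed-mean scaling and
log2 transform, standard array QC metrics (percent present, pairwise
correlation, signal intensity), per-gene logistic regression against
case:control status (plain, sex/age-adjusted, and Huber-robust variants),
conditional logistic regression for 1:1 matched pairs, Benjamini-Hochberg
FDR, cross-cohort intersection, hypergeometric gene-set enrichment, and
clinical-factor association statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from .containers import (ConfigurationError, DataError, ExpressionMatrix,
                         QCReport, case_indicator)

MAX_ABS_BETA = 15.0  # |beta| beyond this on a unit-scale predictor => separation
MAX_ITER = 25


# ---------------------------------------------------------------------------
# normalization and QC
# ---------------------------------------------------------------------------

def normalize_trimmed_mean(raw: ExpressionMatrix, target: float = 100.0,
                           trim_fraction: float = 0.02,
                           log_offset: float = 1.0) -> ExpressionMatrix:
    """Scale each sample to a trimmed mean of ``target``, then log2.

    ``trim_fraction`` is the proportion trimmed from *each* tail before the
    mean.  After scaling, values are transformed as ``log2(x + log_offset)``;
    the default offset of 1 keeps zeros finite.  Output is invariant to any
    positive rescaling of a sample's raw values.
    """
    if raw.scale != "linear":
        raise ConfigurationError("normalize_trimmed_mean expects linear-scale input")
    if not 0.0 <= trim_fraction < 0.5:
        raise ConfigurationError("trim_fraction must be in [0, 0.5)")
    if target <= 0:
        raise ConfigurationError("target must be positive")
    vals = raw.values
    if (vals < 0).any():
        raise DataError("negative raw intensities")
    out = np.empty_like(vals, dtype=float)
    for j, sample in enumerate(raw.samples):
        col = vals[:, j]
        tm = stats.trim_mean(col, trim_fraction)
        if tm <= 0:
            raise DataError(f"sample {sample!r} has non-positive trimmed mean")
        out[:, j] = np.log2(col * (target / tm) + log_offset)
    return ExpressionMatrix(pd.DataFrame(out, index=raw.genes, columns=raw.samples),
                            scale="log2", platform=raw.platform)


@dataclass(frozen=True)
class QCThresholds:
    """Pass/fail cutoffs for :func:`qc_samples` (all configurable; the

    defaults are conventional rather than study-specific)."""

    percent_present_min: float = 60.0
    correlation_min: float = 0.6
    intensity_mad_max: float = 3.0


def qc_samples(matrix: ExpressionMatrix, thresholds: QCThresholds = QCThresholds(),
               present_threshold: float = 1.0) -> QCReport:
    """Per-sample QC: percent present, median pairwise r, median intensity.

    A feature is "present" when its value exceeds ``present_threshold`` (on
    the matrix's own scale).  Intensity passes when the sample's median is
    within ``intensity_mad_max`` robust SDs (1.4826*MAD) of the cohort
    median.  With a single sample the correlation metric is reported as
    missing and ignored, with a warning.
    """
    vals = matrix.values
    n = matrix.n_samples
    pct = (vals > present_threshold).mean(axis=0) * 100.0
    med_int = np.median(vals, axis=0)
    warns = []
    if n >= 2:
        r = np.corrcoef(vals.T)
        np.fill_diagonal(r, np.nan)
        med_r = np.nanmedian(r, axis=1)
    else:
        med_r = np.full(n, np.nan)
        warns.append("single sample: pairwise correlation unavailable")
        warnings.warn(warns[-1], stacklevel=2)

    center = np.median(med_int)
    mad = stats.median_abs_deviation(med_int, scale="normal")
    if mad == 0:
        int_ok = np.full(n, True)
    else:
        int_ok = np.abs(med_int - center) <= thresholds.intensity_mad_max * mad

    pct_ok = pct >= thresholds.percent_present_min
    corr_ok = np.where(np.isnan(med_r), True, med_r >= thresholds.correlation_min)
    passed = pct_ok & corr_ok & int_ok

    metrics = pd.DataFrame({
        "percent_present": pct,
        "median_correlation": med_r,
        "median_intensity": med_int,
        "pass_percent_present": pct_ok,
        "pass_correlation": corr_ok,
        "pass_intensity": int_ok,
        "pass": passed,
    }, index=matrix.samples)
    return QCReport(metrics=metrics,
                    passed=matrix.samples[passed],
                    excluded=matrix.samples[~passed],
                    warnings=warns)


# ---------------------------------------------------------------------------
# logistic fitting machinery
# ---------------------------------------------------------------------------

def _logit_irls(X: np.ndarray, y: np.ndarray, max_iter: int = MAX_ITER,
                tol: float = 1e-10, robust: bool = False, huber_c: float = 1.345):
    """(Robustified) logistic IRLS with an iteration cap.

    With ``robust=True`` observations are down-weighted by Huber weights
    ``min(1, c/|r_i|)`` on deviance residuals, re-evaluated each iteration
    (Pregibon-style resistant fit).  Returns (beta, se, converged).
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    XtWX = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        w = mu * (1 - mu)
        u = np.ones(n)
        if robust:
            with np.errstate(divide="ignore", invalid="ignore"):
                dev = -2 * (y * np.log(np.clip(mu, 1e-12, None))
                            + (1 - y) * np.log(np.clip(1 - mu, 1e-12, None)))
            r = np.sign(y - mu) * np.sqrt(np.clip(dev, 0, None))
            absr = np.abs(r)
            u = np.where(absr > huber_c, huber_c / np.clip(absr, 1e-12, None), 1.0)
        grad = X.T @ (u * (y - mu))
        XtWX = X.T @ (X * (u * w)[:, None])
        try:
            step = np.linalg.solve(XtWX + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 2 * MAX_ABS_BETA:
            break
    if XtWX is None:
        se = np.full(p, np.nan)
    else:
        try:
            se = np.sqrt(np.diag(np.linalg.inv(XtWX + 1e-10 * np.eye(p))))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    return beta, se, converged


def _score_test_p(X, y, col=1):
    """Score (Rao) test p-value for X[:, col] at beta_col = 0, adjusting

    for the remaining columns via the efficient score.  Well-defined even
    under complete separation, where the Wald test degenerates."""
    other = [j for j in range(X.shape[1]) if j != col]
    Z, x = X[:, other], X[:, col]
    beta0, _, _ = _logit_irls(Z, y)
    mu0 = expit(np.clip(Z @ beta0, -30, 30))
    w0 = mu0 * (1 - mu0)
    U = x @ (y - mu0)
    ZtWZ = Z.T @ (Z * w0[:, None])
    try:
        proj = Z @ np.linalg.solve(ZtWZ + 1e-10 * np.eye(Z.shape[1]),
                                   Z.T @ (x * w0))
    except np.linalg.LinAlgError:
        proj = np.zeros_like(x)
    V = float((x - proj) @ (x * w0))
    if V <= 0:
        return 1.0
    return float(2 * stats.norm.sf(abs(U) / np.sqrt(V)))


def _fit_single_gene(X, y, robust):
    """Fit one gene's logistic model; return (beta, se, p, flag) for the

    expression coefficient (column 1 of X)."""
    if not robust:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=MAX_ITER, warn_convergence=False)
            beta = np.asarray(res.params)
            se = np.asarray(res.bse)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            beta, se, converged = _logit_irls(X, y)
    else:
        beta, se, converged = _logit_irls(X, y, robust=True)
    b, s = beta[1], se[1]
    flag = "ok"
    if (not converged) or (not np.isfinite(b)) or abs(b) > MAX_ABS_BETA:
        flag = "separated"
        b = float(np.clip(np.nan_to_num(b, nan=MAX_ABS_BETA), -MAX_ABS_BETA,
                          MAX_ABS_BETA))
        # Wald degenerates under separation; fall back to the score test
        p = _score_test_p(X, y)
    elif np.isfinite(s) and s > 0:
        p = 2 * stats.norm.sf(abs(b / s))
    else:
        p = np.nan
    return b, s, p, flag


def _check_alignment(matrix: ExpressionMatrix, samples: pd.DataFrame):
    missing = [s for s in samples.index if s not in matrix.samples]
    extra = [s for s in matrix.samples if s not in samples.index]
    if missing or extra:
        raise DataError(
            f"matrix/sample id mismatch: missing from matrix {missing}, "
            f"missing from samples {extra}")


def gene_association(matrix: ExpressionMatrix, samples: pd.DataFrame,
                     adjust: str = "none", robust: bool = False) -> pd.DataFrame:
    """Per-gene logistic regression of case:control status on expression.

    ``adjust="sex_age"`` adds sex and age covariates (records with missing
    age are dropped for the fit, with a warning).  ``robust=True`` switches
    to Huber-down-weighted estimation.  Returns an association table indexed
    by gene with columns beta, se, p_unadjusted or p_adjusted, q_bh, flag.
    Degenerate (constant) genes get beta 0, p 1; complete separation is
    flagged with a finite capped beta.
    """
    if adjust not in ("none", "sex_age"):
        raise ConfigurationError(f"unknown adjust mode {adjust!r}")
    _check_alignment(matrix, samples)
    samples = samples.loc[list(matrix.samples)]
    if adjust == "sex_age" and samples["age_missing"].any():
        n_drop = int(samples["age_missing"].sum())
        warnings.warn(f"dropping {n_drop} record(s) with missing age from "
                      "sex/age-adjusted fits", stacklevel=2)
        samples = samples[~samples["age_missing"]]
    y = case_indicator(samples)
    if len(np.unique(y)) < 2:
        raise DataError("need both cases and controls")
    vals = matrix.subset(samples=samples.index).values
    n = len(samples)
    if adjust == "sex_age":
        sexm = (samples["sex"] == "M").to_numpy(float)
        age = samples["age"].to_numpy(float)
        covar = np.column_stack([np.ones(n), np.zeros(n), sexm, age])
    else:
        covar = np.column_stack([np.ones(n), np.zeros(n)])

    rows = []
    pcol = "p_adjusted" if adjust == "sex_age" else "p_unadjusted"
    for i, gene in enumerate(matrix.genes):
        x = vals[i]
        if np.ptp(x) == 0:
            rows.append((gene, 0.0, np.nan, 1.0, "degenerate"))
            continue
        X = covar.copy()
        X[:, 1] = x
        b, s, p, flag = _fit_single_gene(X, y, robust)
        rows.append((gene, b, s, p, flag))
    out = pd.DataFrame(rows, columns=["gene", "beta", "se", pcol, "flag"])
    out = out.set_index("gene")
    out["q_bh"] = bh_fdr(out[pcol].fillna(1.0).to_numpy())
    return out


# ---------------------------------------------------------------------------
# conditional logistic regression (1:1 matched pairs)
# ---------------------------------------------------------------------------

def _conditional_logit_1to1(d: np.ndarray, max_iter: int = MAX_ITER,
                            tol: float = 1e-12):
    """Maximise the 1:1 matched-pair conditional likelihood.

    With within-pair expression differences ``d_i = x_case - x_control`` the
    conditional likelihood is ``prod_i 1 / (1 + exp(-beta d_i))``; Newton
    iteration on its log.  Returns (beta, se, converged).
    """
    beta = 0.0
    converged = False
    for _ in range(max_iter):
        mu = expit(np.clip(beta * d, -30, 30))
        grad = np.sum(d * (1 - mu))
        info = np.sum(d * d * mu * (1 - mu))
        if info <= 0:
            break
        step = grad / info
        beta += step
        if abs(step) < tol:
            converged = True
            break
        if abs(beta) > 2 * MAX_ABS_BETA:
            break
    mu = expit(np.clip(beta * d, -30, 30))
    info = np.sum(d * d * mu * (1 - mu))
    se = 1.0 / np.sqrt(info) if info > 0 else np.nan
    return beta, se, converged


def paired_gene_association(matrix: ExpressionMatrix,
                            samples: pd.DataFrame) -> pd.DataFrame:
    """Conditional logistic regression per gene on 1:1 matched pairs.

    Every pair id must label exactly one case and one control.  Reports the
    Wald p as ``p_unadjusted`` plus a ``p_score`` column from the score test
    at beta=0 (``z = sum d / sqrt(sum d^2)``).  Pairs with all differences of
    one sign are flagged ``separated`` with a capped finite beta; all-zero
    differences give beta 0, p 1 (``degenerate``).
    """
    if "pair_id" not in samples.columns:
        raise DataError("paired analysis requires a pair_id column")
    _check_alignment(matrix, samples)
    paired = samples[samples["pair_id"].notna()]
    case_ids, control_ids = [], []
    for pid, grp in paired.groupby("pair_id"):
        st = grp["status"]
        if (st == "case").sum() != 1 or (st == "control").sum() != 1:
            raise DataError(f"pair {pid!r} is not one case + one control")
        case_ids.append(grp.index[st == "case"][0])
        control_ids.append(grp.index[st == "control"][0])
    if not case_ids:
        raise DataError("no complete pairs found")
    dmat = (matrix.subset(samples=case_ids).values
            - matrix.subset(samples=control_ids).values)

    rows = []
    for i, gene in enumerate(matrix.genes):
        d = dmat[i]
        ss = float(np.sum(d * d))
        if ss == 0:
            rows.append((gene, 0.0, np.nan, 1.0, 1.0, "degenerate"))
            continue
        z_score = float(np.sum(d)) / np.sqrt(ss)
        p_score = 2 * stats.norm.sf(abs(z_score))
        nz = d[d != 0]
        if np.all(nz > 0) or np.all(nz < 0):
            beta = float(np.sign(nz[0]) * MAX_ABS_BETA)
            rows.append((gene, beta, np.nan, p_score, p_score, "separated"))
            continue
        beta, se, converged = _conditional_logit_1to1(d)
        flag = "ok" if converged and abs(beta) <= MAX_ABS_BETA else "separated"
        beta = float(np.clip(beta, -MAX_ABS_BETA, MAX_ABS_BETA))
        p_wald = 2 * stats.norm.sf(abs(beta / se)) if np.isfinite(se) else p_score
        rows.append((gene, beta, se, p_wald, p_score, flag))
    out = pd.DataFrame(rows, columns=["gene", "beta", "se", "p_unadjusted",
                                      "p_score", "flag"]).set_index("gene")
    out["q_bh"] = bh_fdr(out["p_unadjusted"].fillna(1.0).to_numpy())
    return out


# ---------------------------------------------------------------------------
# multiplicity, intersection, enrichment
# ---------------------------------------------------------------------------

def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def intersect_discovery(res_a: pd.DataFrame, res_b: pd.DataFrame,
                        alpha: float = 0.05,
                        column: str = "p_unadjusted") -> set:
    """Genes significant (``p < alpha``) in both discovery cohorts."""
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must be in (0, 1)")
    sig_a = set(res_a.index[res_a[column] < alpha])
    sig_b = set(res_b.index[res_b[column] < alpha])
    return sig_a & sig_b


def enrich_hypergeometric(study, annotation: dict, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    ``study`` must be a subset of ``universe``; each annotation set is
    intersected with the universe first.  Returns a table (term, overlap,
    set_size, p, q_bh) with BH correction across terms.
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    study = set(study)
    stray = study - universe
    if stray:
        raise DataError(f"study genes outside universe: {sorted(stray)[:5]}")
    M, N = len(universe), len(study)
    rows = []
    for term, genes in annotation.items():
        term_set = set(genes) & universe
        k = len(term_set & study)
        # P[X >= k] drawing N from M with len(term_set) successes
        p = float(stats.hypergeom.sf(k - 1, M, len(term_set), N))
        rows.append((term, k, len(term_set), min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "overlap", "set_size", "p"])
    out = out.set_index("term")
    out["q_bh"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    return out


# ---------------------------------------------------------------------------
# clinical factors
# ---------------------------------------------------------------------------

def contingency_chi2(table) -> tuple:
    """Pearson chi-square (no continuity correction) on a k x 2 table.

    Returns (statistic, p, dof)."""
    table = np.asarray(table, dtype=float)
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p), int(dof)


def clinical_factor_association(samples: pd.DataFrame, factors=None,
                                multivariate=None) -> pd.DataFrame:
    """Case:control association of clinical/demographic factors.

    Continuous/binary factors: univariate logistic Wald p.  Categorical
    (object dtype) factors: Pearson chi-square on the contingency table.
    ``multivariate`` names factors for a joint logistic model whose Wald p
    values are reported in ``p_multivariate``.  Zero-variance factors are
    flagged ``degenerate``.
    """
    y = case_indicator(samples)
    if len(np.unique(y)) < 2:
        raise DataError("need both cases and controls")
    if factors is None:
        factors = [c for c in samples.columns
                   if c not in ("status", "age_missing", "pair_id")]
    rows = []
    for f in factors:
        col = samples[f]
        mask = col.notna()
        if col.dropna().nunique() <= 1:
            rows.append((f, "degenerate", np.nan, np.nan, np.nan))
            continue
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            tab = pd.crosstab(col[mask], samples.loc[mask, "status"])
            stat, p, _ = contingency_chi2(tab.to_numpy())
            rows.append((f, "categorical", np.nan, np.nan, p))
        else:
            x = col[mask].astype(float).to_numpy()
            X = np.column_stack([np.ones(mask.sum()), x])
            b, s, p, flag = _fit_single_gene(X, y[mask.to_numpy()], robust=False)
            rows.append((f, "continuous" if flag == "ok" else flag, b, s, p))
    out = pd.DataFrame(rows, columns=["factor", "kind", "beta", "se", "p"])
    out = out.set_index("factor")

    if multivariate:
        sub = samples[list(multivariate)].apply(pd.to_numeric, errors="coerce")
        mask = sub.notna().all(axis=1)
        X = sm.add_constant(sub[mask].to_numpy(float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y[mask.to_numpy()], X).fit(disp=0, maxiter=100)
        pvals = pd.Series(np.asarray(res.pvalues)[1:], index=list(multivariate))
        out["p_multivariate"] = pvals.reindex(out.index)
    return out
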