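"""Synthetic case:control cohort generator.

Emulates the statistical structure a whole-blood CAD expression study
assumes, so every downstream stage is testable without any real data:

* disease status follows a logistic model in age and sex;
* genes come in co-expression clusters driven by latent cell-type activity
  (neutrophil, T/B lymphocyte, NK, eosinophil) so cluster members correlate
  with each other and with the emitted blood counts;
* CAD shifts expression per cluster, optionally with opposite sign in men
  and women (neutrophil genes) or sex-independently (lymphocyte genes);
* in diabetics the CAD shift is multiplied by ``diabetic_effect_multiplier``
  (0 abolishes the association, the mechanism behind disjoint significant
  gene sets in diabetic/non-diabetic subsets);
* RT-PCR measurement is emulated as triplicate draws aggregated by median,
  with occasional gross outliers.

Expression is generated directly on the log2 scale; PCR values are
interpreted as -dCt-like quantities on the same scale (higher = more
transcript), so one matrix type serves both platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .containers import ConfigurationError, DataError, ExpressionMatrix

CELL_TYPES = ("neutrophil", "lymphocyte_T", "lymphocyte_B", "NK", "eosinophil", "none")
SEX_MODES = ("both", "antagonistic", "male_only", "female_only")

# blood-count marginals (10^3 cells/uL), chosen to match typical adult
# angiography-cohort values: neutrophils ~4 +/- 1.3, lymphocytes ~1.9 +/- 0.65
NEUTROPHIL_MEAN, NEUTROPHIL_SD = 4.0, 1.3
LYMPHOCYTE_MEAN, LYMPHOCYTE_SD = 1.9, 0.65

_BASELINE_SEED = 20110328  # fixed stream for gene-intrinsic baselines


@dataclass(frozen=True)
class ClusterSpec:
    """A co-expression cluster: ``size`` genes driven by one cell type."""

    cluster_id: str
    size: int
    driver: str = "none"
    loading: float = 0.7

    def __post_init__(self):
        if self.driver not in CELL_TYPES:
            raise ConfigurationError(f"unknown cell-type driver {self.driver!r}")
        if self.size < 1:
            raise ConfigurationError("cluster size must be >= 1")


@dataclass(frozen=True)
class EffectSpec:
    """Planted CAD expression shift (log2 units, cases vs controls).

    ``sex_mode``:
      * ``both`` — same shift in men and women,
      * ``antagonistic`` — ``+shift`` in men, ``-shift`` in women,
      * ``male_only`` / ``female_only`` — shift in one sex only.
    """

    cluster_id: str
    shift: float
    sex_mode: str = "both"

    def __post_init__(self):
        if self.sex_mode not in SEX_MODES:
            raise ConfigurationError(f"unknown sex_mode {self.sex_mode!r}")


@dataclass
class SimulationConfig:
    """All generative knobs for one synthetic cohort.

    Defaults mirror the development-cohort conditions: ~1/3 cases, mostly
    male, cases older (age odds ratio per decade ~2, male odds ratio ~2.5),
    unit log2 residual noise, triplicate PCR noise of 0.2 Ct.
    """

    n_samples: int = 640
    case_fraction: float = 0.36
    male_fraction: float = 0.58
    age_mean: float = 60.0
    age_sd: float = 12.0
    age_or_per_decade: float = 2.0
    male_or: float = 2.5
    n_genes: int = 113
    cluster_spec: list = field(default_factory=list)
    effect_spec: list = field(default_factory=list)
    diabetic_fraction: float = 0.0
    diabetic_effect_multiplier: float = 1.0
    noise_sd: float = 1.0
    pcr_replicate_sd: float = 0.2
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("case_fraction", "male_fraction", "diabetic_fraction",
                     "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.n_samples < 2 or self.n_genes < 1:
            raise ConfigurationError("need n_samples >= 2 and n_genes >= 1")
        if self.noise_sd < 0 or self.pcr_replicate_sd < 0:
            raise ConfigurationError("noise sd must be >= 0")
        self.cluster_spec = [c if isinstance(c, ClusterSpec) else ClusterSpec(*c)
                             for c in self.cluster_spec]
        self.effect_spec = [e if isinstance(e, EffectSpec) else EffectSpec(*e)
                            for e in self.effect_spec]
        total = sum(c.size for c in self.cluster_spec)
        if total > self.n_genes:
            raise ConfigurationError(
                f"cluster sizes sum to {total} > n_genes={self.n_genes}")
        ids = [c.cluster_id for c in self.cluster_spec]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate cluster ids")
        known = set(ids)
        for e in self.effect_spec:
            if e.cluster_id not in known:
                raise ConfigurationError(
                    f"effect references unknown cluster {e.cluster_id!r}")


def _solve_intercept(age, male, config) -> float:
    b_age = np.log(config.age_or_per_decade) / 10.0
    b_male = np.log(config.male_or)
    lin = b_age * (age - config.age_mean) + b_male * male
    if config.case_fraction in (0.0, 1.0):
        return -50.0 if config.case_fraction == 0.0 else 50.0

    def gap(b0):
        return expit(b0 + lin).mean() - config.case_fraction

    return brentq(gap, -30, 30)


def generate_cohort(config: SimulationConfig):
    """Generate one synthetic cohort.

    Returns
    -------
    (matrix, samples, latent, truth)
        ``matrix`` — log2-scale :class:`ExpressionMatrix` (rtpcr platform);
        ``samples`` — phenotype table (status, sex, age, diabetic, counts);
        ``latent`` — per-sample cell-type activities and latent fractions
        (ground truth for recovery tests);
        ``truth`` — per-gene table of planted structure: cluster, driver,
        loading, and effective CAD shift in men and women.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    sample_ids = [f"S{i:04d}" for i in range(n)]
    male = (rng.random(n) < config.male_fraction).astype(float)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 25.0, 90.0)
    b0 = _solve_intercept(age, male, config)
    b_age = np.log(config.age_or_per_decade) / 10.0
    b_male = np.log(config.male_or)
    p_case = expit(b0 + b_age * (age - config.age_mean) + b_male * male)
    case = (rng.random(n) < p_case).astype(float)
    diabetic = (rng.random(n) < config.diabetic_fraction).astype(bool)

    # latent per-cell-type activities (z-scores) drive both counts and genes
    activity = {ct: rng.normal(size=n) for ct in CELL_TYPES if ct != "none"}
    neut = np.clip(NEUTROPHIL_MEAN + NEUTROPHIL_SD * activity["neutrophil"], 0.3, None)
    lymph_act = 0.5 * (activity["lymphocyte_T"] + activity["lymphocyte_B"])
    lymph = np.clip(LYMPHOCYTE_MEAN + LYMPHOCYTE_SD * lymph_act, 0.2, None)

    # per-gene structure
    gene_rows = []
    assigned = 0
    effects = {e.cluster_id: e for e in config.effect_spec}
    for c in config.cluster_spec:
        eff = effects.get(c.cluster_id)
        for j in range(c.size):
            gene_rows.append((f"G_{c.cluster_id}_{j:03d}", c.cluster_id,
                              c.driver, c.loading, eff))
            assigned += 1
    for j in range(config.n_genes - assigned):
        gene_rows.append((f"G_bg_{j:04d}", "background", "none", 0.0, None))

    genes, clusters, drivers, loadings = [], [], [], []
    shift_m, shift_f = [], []
    for g, cl, dr, ld, eff in gene_rows:
        genes.append(g)
        clusters.append(cl)
        drivers.append(dr)
        loadings.append(ld)
        if eff is None:
            sm = sf = 0.0
        elif eff.sex_mode == "both":
            sm = sf = eff.shift
        elif eff.sex_mode == "antagonistic":
            sm, sf = eff.shift, -eff.shift
        elif eff.sex_mode == "male_only":
            sm, sf = eff.shift, 0.0
        else:
            sm, sf = 0.0, eff.shift
        shift_m.append(sm)
        shift_f.append(sf)

    # baselines are a property of the gene panel, not of the cohort draw:
    # a fixed stream makes them reproducible across seeds so locked
    # coefficients transport between cohorts of the same panel
    baseline = np.random.default_rng(_BASELINE_SEED).uniform(
        6.0, 12.0, size=len(genes))
    truth = pd.DataFrame({
        "gene": genes, "cluster": clusters, "driver": drivers,
        "loading": loadings, "shift_male": shift_m, "shift_female": shift_f,
        "baseline": baseline,
    }).set_index("gene")
    expr = np.empty((len(genes), n))
    eff_mult = np.where(diabetic, config.diabetic_effect_multiplier, 1.0)
    for i, g in enumerate(genes):
        x = np.full(n, baseline[i])
        if drivers[i] != "none":
            x = x + loadings[i] * activity[drivers[i]]
        shift = np.where(male == 1, shift_m[i], shift_f[i])
        x = x + case * shift * eff_mult
        x = x + rng.normal(scale=config.noise_sd, size=n)
        expr[i] = x

    matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=sample_ids),
        scale="log2", platform="rtpcr")
    samples = pd.DataFrame({
        "status": np.where(case == 1, "case", "control"),
        "sex": np.where(male == 1, "M", "F"),
        "age": age,
        "diabetic": diabetic,
        "neutrophil_count": neut,
        "lymphocyte_count": lymph,
    }, index=pd.Index(sample_ids, name="sample_id"))
    samples["age_missing"] = False
    latent = pd.DataFrame(
        {f"activity_{ct}": act for ct, act in activity.items()},
        index=samples.index)
    latent["neutrophil_fraction"] = neut / (neut + lymph)
    latent["lymphocyte_fraction"] = lymph / (neut + lymph)
    latent["p_case"] = p_case
    return matrix, samples, latent, truth


def simulate_pcr_panel(truth_expression: ExpressionMatrix, replicate_sd: float,
                       outlier_rate: float = 0.0, seed: int = 0,
                       n_replicates: int = 3,
                       outlier_shift: float = 10.0) -> ExpressionMatrix:
    """Emulate RT-PCR measurement: replicate wells aggregated by median.

    Each gene x sample well is drawn ``n_replicates`` times with Gaussian
    replicate noise; each replicate is independently contaminated (probability
    ``outlier_rate``) by a fixed ``+outlier_shift`` gross error.  The median
    of the replicates is reported, which is what makes occasional outliers
    harmless compared with mean aggregation.
    """
    if replicate_sd < 0:
        raise ConfigurationError("replicate_sd must be >= 0")
    if not 0.0 <= outlier_rate <= 1.0:
        raise ConfigurationError("outlier_rate outside [0, 1]")
    rng = np.random.default_rng(seed)
    truth = truth_expression.values
    reps = truth[None, :, :] + rng.normal(
        scale=replicate_sd, size=(n_replicates,) + truth.shape) if replicate_sd > 0 \
        else np.broadcast_to(truth, (n_replicates,) + truth.shape).copy()
    if outlier_rate > 0:
        mask = rng.random(reps.shape) < outlier_rate
        reps = reps + mask * outlier_shift
    med = np.median(reps, axis=0)
    return ExpressionMatrix(
        pd.DataFrame(med, index=truth_expression.genes,
                     columns=truth_expression.samples),
        scale=truth_expression.scale, platform="rtpcr")


def match_pairs(samples: pd.DataFrame, age_tolerance: float = 5.0):
    """Greedy sex-identical, age-sorted case:control matching.

    Within each sex, cases are swept in ascending age order and each is
    matched to the *youngest* unused control whose age lies within
    ``age_tolerance`` years.  For interval compatibility on a line this
    sweep is cardinality-optimal (exchange argument), unlike a
    nearest-age-first greedy.  Returns a list of ``(case_id, control_id)``
    pairs ordered by case age within sex; warns when some cases cannot be
    matched.
    """
    if age_tolerance < 0:
        raise ConfigurationError("age_tolerance must be >= 0")
    cases = samples[samples["status"] == "case"]
    controls = samples[samples["status"] == "control"]
    if cases.empty or controls.empty:
        raise DataError("need both cases and controls to match pairs")
    pairs = []
    for sex in ("F", "M"):
        cs = cases[cases["sex"] == sex].sort_values(["age", "sex"])
        ct = controls[controls["sex"] == sex].sort_values(["age", "sex"])
        ct_age = ct["age"].to_numpy(float)
        ct_ids = list(ct.index)
        used = np.zeros(len(ct_ids), dtype=bool)
        for cid, crow in cs.iterrows():
            lo, hi = crow["age"] - age_tolerance, crow["age"] + age_tolerance
            ok = np.flatnonzero(~used & (ct_age >= lo) & (ct_age <= hi))
            if len(ok):
                j = ok[0]  # youngest compatible control
                used[j] = True
                pairs.append((cid, ct_ids[j]))
    if len(pairs) < len(cases):
        warnings.warn(
            f"matched {len(pairs)} of {len(cases)} cases within "
            f"{age_tolerance} years", stacklevel=2)
    return pairs


def assign_pair_ids(samples: pd.DataFrame, pairs) -> pd.DataFrame:
    """Return a copy of the sample table with ``pair_id`` set from ``pairs``."""
    out = samples.copy()
    out["pair_id"] = pd.Series(dtype=object)
    for k, (cid, tid) in enumerate(pairs):
        out.loc[cid, "pair_id"] = f"P{k:04d}"
        out.loc[tid, "pair_id"] = f"P{k:04d}"
    return out


def bayes_auc(config: SimulationConfig, n_mc: int = 20000,
              seed: int = 123456, projection=None) -> float:
    """Monte-Carlo estimate of the generative (Bayes-optimal) AUC.

    Draws a large fresh cohort from ``config`` and scores each sample with
    the *true* posterior log-odds of case status given the observed
    features, age and sex.  The class-conditional expression distribution
    is Gaussian with a shared covariance (latent cell-type factors plus
    independent noise), so per sex the optimal feature score is the linear
    discriminant ``w_s' f`` with ``w_s = Cov_f^{-1} delta_f``, added to the
    logit of the age/sex case probability.

    ``projection`` restricts the oracle to what a classifier actually
    observes: either a single (features x genes) DataFrame (columns indexed
    like the truth table) applied to both sexes — e.g. ratio-term contrasts
    — or a ``{"M": A_m, "F": A_f}`` pair when the feature set is
    sex-specific.  With ``projection=None`` the oracle sees every gene and
    upper-bounds any classifier on this world.

    Only defined for non-diabetic configurations (a diabetic multiplier
    would make the shift sample-dependent).
    """
    from dataclasses import replace

    from sklearn.metrics import roc_auc_score

    if config.diabetic_fraction != 0.0:
        raise ConfigurationError("bayes_auc requires diabetic_fraction == 0")
    cfg = replace(config, n_samples=n_mc, seed=seed)
    matrix, samples, latent, truth = generate_cohort(cfg)
    g = truth.shape[0]
    cov = np.diag(np.full(g, float(config.noise_sd) ** 2))
    for ct in sorted(set(truth["driver"]) - {"none"}):
        v = np.where(truth["driver"].to_numpy() == ct,
                     truth["loading"].to_numpy(), 0.0)
        cov = cov + np.outer(v, v)
    x = matrix.values.T  # samples x genes
    mu0 = truth["baseline"].to_numpy()
    prior = np.log(latent["p_case"] / (1 - latent["p_case"])).to_numpy()
    male = (samples["sex"] == "M").to_numpy()

    if projection is None:
        proj = {"M": None, "F": None}
    elif isinstance(projection, dict):
        proj = projection
    else:
        proj = {"M": projection, "F": projection}

    score = np.empty(len(samples))
    for sex, mask in (("M", male), ("F", ~male)):
        delta = truth["shift_male" if sex == "M" else "shift_female"].to_numpy()
        A = proj[sex]
        if A is None:
            feats = x[mask] - mu0
            cov_f, delta_f = cov, delta
        else:
            A = A.reindex(columns=truth.index).fillna(0.0) \
                if hasattr(A, "reindex") else pd.DataFrame(A, columns=truth.index)
            Av = A.to_numpy(float)
            feats = (x[mask] - mu0) @ Av.T
            cov_f = Av @ cov @ Av.T
            delta_f = Av @ delta
        w = np.linalg.solve(cov_f, delta_f)
        score[mask] = (feats - delta_f / 2.0) @ w
    score = score + prior
    y = (samples["status"] == "case").to_numpy(int)
    return float(roc_auc_score(y, score))


def term_projection(terms, gene_index) -> pd.DataFrame:
    """Contrast matrix mapping genes to ratio-term values.

    One row per term: numerator weights positive, denominator weights
    negative; columns follow ``gene_index`` (extra genes get weight 0).
    """
    A = pd.DataFrame(0.0, index=[t.id for t in terms], columns=list(gene_index))
    for t in terms:
        for gset, sign in ((t.numerator, 1.0), (t.denominator, -1.0)):
            for gene, wt in zip(gset.genes, gset.weights):
                A.loc[t.id, gene] += sign * gset.sign * wt
    return A


def null_config(n_samples: int = 400, n_genes: int = 1000, seed: int = 0,
                **kw) -> SimulationConfig:
    """A no-effect cohort configuration for type-I-error checks."""
    return SimulationConfig(n_samples=n_samples, n_genes=n_genes,
                            cluster_spec=[], effect_spec=[], seed=seed, **kw)
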