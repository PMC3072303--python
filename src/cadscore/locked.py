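"""The locked 23-gene / 6-term CAD score.

Structure (fixed, validated at load):

* Term 1 (both sexes): up-regulated neutrophil genes (CASP5, TNFAIP6,
  IL18RAP) minus down-regulated neutrophil genes (TNFRSF10C, IL8RB, TLR4,
  KCNE3);
* Term 2: innate-immunity genes (S100A8, S100A12, CLEC4E) normalized to
  RPL28 in men and to the CAD-insensitive neutrophil genes AQP9 + NCF4 in
  women;
* Term 3 (both): NK-cell genes (KLRC4, SLAMF7) minus T-cell genes (TMC8,
  CD3D);
* Term 4 (both): B-cell genes (CD79B, SPIB) minus the same T-cell genes;
* Term 5 (both): AF289562 (probe A_24_P128361) normalized to HNRNPF + TFCP2;
* Term 6 (men only): TSPAN16 (AF161365) normalized to HNRNPF + TFCP2.

Score = intercept + sum_t w_t * term_t + sex_male coefficient
        + beta_m * age          (men)
        + beta_f * max(age-60, 0)  (women; no age effect below the knot),
optionally passed through a monotone affine transform.

Expression inputs are log2 / -dCt-like: HIGHER value = MORE transcript
(note Ct itself is inversely related to abundance).

The packaged default coefficients are fitted on a *synthetic* reference
cohort (see ``scripts/make_reference_coefficients.py``) and are
non-clinical placeholders; supply your own coefficient file for any real
use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .containers import ConfigurationError, DataError, ExpressionMatrix
from .model import roc_auc

#: accession <-> symbol aliases; resolution is exact match on either name
ALIASES = {"AF289562": "A_24_P128361", "A_24_P128361": "AF289562",
           "TSPAN16": "AF161365", "AF161365": "TSPAN16"}

NORMALIZATION_GENES = frozenset({"RPL28", "HNRNPF", "TFCP2"})

#: term id -> (numerator component, denominator component(s) by sex, applicability)
TERM_MAP = {
    "T1": {"num": "1a", "den": {"M": "1b", "F": "1b"}, "sex": "both"},
    "T2": {"num": "2a", "den": {"M": "2b", "F": "2c"}, "sex": "both"},
    "T3": {"num": "3a", "den": {"M": "3b", "F": "3b"}, "sex": "both"},
    "T4": {"num": "4a", "den": {"M": "4b", "F": "4b"}, "sex": "both"},
    "T5": {"num": "5a", "den": {"M": "5b", "F": "5b"}, "sex": "both"},
    "T6": {"num": "6a", "den": {"M": "6b", "F": "6b"}, "sex": "male_only"},
}


@dataclass(frozen=True)
class LockedStructure:
    """Registry of term-component codes -> gene lists, plus the term map."""

    components: dict
    term_map: dict = field(default_factory=lambda: dict(TERM_MAP))

    def __post_init__(self):
        genes = self.all_genes
        if len(genes) != 23:
            raise ConfigurationError(
                f"locked structure must contain 23 unique genes, got {len(genes)}")
        if set(self.normalization_genes) != set(NORMALIZATION_GENES):
            raise ConfigurationError("normalization genes must be RPL28/HNRNPF/TFCP2")
        if len(self.informative_genes) != 20:
            raise ConfigurationError("locked structure must have 20 informative genes")
        if len(self.term_map) != 6:
            raise ConfigurationError("locked structure must define 6 terms")
        needed = {t["num"] for t in self.term_map.values()}
        needed |= {c for t in self.term_map.values() for c in t["den"].values()}
        missing = needed - set(self.components)
        if missing:
            raise ConfigurationError(f"term map references unknown components {missing}")

    @property
    def all_genes(self) -> tuple:
        seen = dict.fromkeys(g for comp in self.components.values() for g in comp)
        return tuple(seen)

    @property
    def normalization_genes(self) -> tuple:
        return tuple(g for g in self.all_genes if g in NORMALIZATION_GENES)

    @property
    def informative_genes(self) -> tuple:
        return tuple(g for g in self.all_genes if g not in NORMALIZATION_GENES)

    @property
    def n_terms(self) -> int:
        return len(self.term_map)

    def term_sex(self, term_id: str) -> str:
        return self.term_map[term_id]["sex"]


def locked_term_definitions(components: dict | None = None) -> LockedStructure:
    """The locked component registry, parsed from the packaged panel table.

    Passing a modified ``components`` registry re-validates it; any edit
    violating the structural invariants raises at load.
    """
    if components is None:
        from .panel import load_reference_panel
        table = load_reference_panel()
        components: dict[str, list] = {}
        for gene, row in table.iterrows():
            codes = row.get("algorithm_term")
            if pd.isna(codes) or not str(codes).strip():
                continue
            for code in str(codes).split(","):
                components.setdefault(code.strip(), []).append(gene)
        components = {k: tuple(v) for k, v in components.items()}
        # 4b shares its genes with 3b (T-cell denominator used by two terms)
        components.setdefault("4b", components.get("3b", ()))
    else:
        components = {k: tuple(v) for k, v in components.items()}
    return LockedStructure(components=components)


# ---------------------------------------------------------------------------
# coefficients
# ---------------------------------------------------------------------------

@dataclass
class LockedCoefficients:
    """Numeric weights for the locked structure.

    ``term_weights`` maps term id to either a float or a per-sex mapping
    ``{"M": w, "F": w}``.  ``transform = (a, b)`` applies ``a*score + b``
    with a > 0 (identity by default).
    """

    intercept: float = 0.0
    term_weights: dict = field(default_factory=dict)
    sex_coefficient: float = 0.0
    male_age_slope: float = 0.0
    female_age_hinge_slope: float = 0.0
    knot: float = 60.0
    transform: tuple = (1.0, 0.0)

    def __post_init__(self):
        a, b = self.transform
        if not (np.isfinite(a) and np.isfinite(b)) or a <= 0:
            raise ConfigurationError("transform must be monotone (a > 0, finite)")
        for v in [self.intercept, self.sex_coefficient, self.male_age_slope,
                  self.female_age_hinge_slope, self.knot]:
            if not np.isfinite(v):
                raise ConfigurationError("non-finite coefficient")

    def weight(self, term_id: str, sex: str) -> float:
        w = self.term_weights.get(term_id, 0.0)
        if isinstance(w, dict):
            return float(w.get(sex, 0.0))
        return float(w)

    def save(self, path) -> None:
        payload = {"intercept": self.intercept,
                   "term_weights": self.term_weights,
                   "sex_coefficient": self.sex_coefficient,
                   "male_age_slope": self.male_age_slope,
                   "female_age_hinge_slope": self.female_age_hinge_slope,
                   "knot": self.knot,
                   "transform": list(self.transform)}
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# cadscore locked-model coefficients\n")
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "LockedCoefficients":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        payload.pop("seed", None)
        payload.pop("note", None)
        payload["transform"] = tuple(payload.get("transform", (1.0, 0.0)))
        return cls(**payload)


def default_coefficients() -> LockedCoefficients:
    """Packaged coefficients fitted on the synthetic reference cohort.

    Synthetic and non-clinical: for demonstrations and tests only."""
    ref = resources.files("cadscore.reference").joinpath("locked_coefficients.txt")
    with resources.as_file(ref) as path:
        return LockedCoefficients.load(path)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _resolve(names, available: set) -> dict:
    """Map each required gene name to the matching key in ``available``

    (exact match on either the symbol or its accession alias)."""
    mapping, missing = {}, []
    for g in names:
        if g in available:
            mapping[g] = g
        elif g in ALIASES and ALIASES[g] in available:
            mapping[g] = ALIASES[g]
        else:
            missing.append(g)
    if missing:
        raise DataError(f"missing locked-score genes: {missing}")
    return mapping


def _component_mean(expression: dict, structure: LockedStructure,
                    code: str, name_map: dict) -> float:
    genes = structure.components[code]
    return float(np.mean([expression[name_map[g]] for g in genes]))


def compute_locked_score(expression, sex: str, age: float,
                         coefficients: LockedCoefficients,
                         structure: LockedStructure | None = None) -> float:
    """Score one sample from its 23 locked-gene log-scale values.

    ``expression`` maps gene symbol (or accession alias) to a log2 / -dCt
    value.  Term 2 uses the RPL28 denominator for men and AQP9+NCF4 for
    women; Term 6 contributes only for men.  Women below the age knot get
    no age contribution.
    """
    if sex not in ("M", "F"):
        raise DataError(f"unknown sex code {sex!r}")
    if not age > 0:
        raise DataError("age must be positive")
    structure = structure or locked_term_definitions()
    expression = dict(expression)
    name_map = _resolve(structure.all_genes, set(expression))
    score = coefficients.intercept
    for term_id, spec in structure.term_map.items():
        if spec["sex"] == "male_only" and sex == "F":
            continue
        if spec["sex"] == "female_only" and sex == "M":
            continue
        num = _component_mean(expression, structure, spec["num"], name_map)
        den = _component_mean(expression, structure, spec["den"][sex], name_map)
        score += coefficients.weight(term_id, sex) * (num - den)
    if sex == "M":
        score += coefficients.sex_coefficient
        score += coefficients.male_age_slope * age
    else:
        score += coefficients.female_age_hinge_slope * max(age - coefficients.knot, 0.0)
    a, b = coefficients.transform
    out = a * score + b
    if not np.isfinite(out):
        raise DataError("non-finite score")
    return float(out)


def term_values(matrix: ExpressionMatrix, samples: pd.DataFrame,
                structure: LockedStructure | None = None) -> pd.DataFrame:
    """Sex-resolved locked term values per sample (columns T1..T6).

    Sex-restricted terms are NaN where inapplicable."""
    structure = structure or locked_term_definitions()
    name_map = _resolve(structure.all_genes, set(matrix.genes))
    samples = samples.loc[list(matrix.samples)]
    male = (samples["sex"] == "M").to_numpy()
    comp_means = {code: matrix.data.loc[[name_map[g] for g in genes]].mean(axis=0)
                  for code, genes in structure.components.items()}
    out = {}
    for term_id, spec in structure.term_map.items():
        num = comp_means[spec["num"]]
        den_m = comp_means[spec["den"]["M"]]
        den_f = comp_means[spec["den"]["F"]]
        val = np.where(male, num - den_m, num - den_f)
        if spec["sex"] == "male_only":
            val = np.where(male, val, np.nan)
        elif spec["sex"] == "female_only":
            val = np.where(~male, val, np.nan)
        out[term_id] = val
    return pd.DataFrame(out, index=samples.index)


def score_batch(matrix: ExpressionMatrix, samples: pd.DataFrame,
                coefficients: LockedCoefficients,
                structure: LockedStructure | None = None):
    """Vectorized locked scoring of a cohort.

    Returns ``(table, roc)``: the table holds sample id, score, sex, age
    and the term values; ``roc`` is ``(auc, (lo, hi))`` against status when
    a status column is present, else None.  Missing genes raise with the
    full list of missing symbols (no silent imputation).
    """
    structure = structure or locked_term_definitions()
    samples = samples.loc[list(matrix.samples)]
    bad_age = samples.index[~(samples["age"] > 0)].tolist()
    if bad_age:
        raise DataError(f"missing/invalid age for samples {bad_age}")
    tv = term_values(matrix, samples, structure)
    male = (samples["sex"] == "M").to_numpy()
    age = samples["age"].to_numpy(float)
    score = np.full(len(samples), coefficients.intercept)
    for term_id in structure.term_map:
        w = np.where(male,
                     coefficients.weight(term_id, "M"),
                     coefficients.weight(term_id, "F"))
        score = score + w * np.nan_to_num(tv[term_id].to_numpy(), nan=0.0)
    score = score + np.where(male, coefficients.sex_coefficient, 0.0)
    score = score + np.where(male, coefficients.male_age_slope * age,
                             coefficients.female_age_hinge_slope
                             * np.maximum(age - coefficients.knot, 0.0))
    a, b = coefficients.transform
    score = a * score + b
    table = pd.DataFrame({"score": score, "sex": samples["sex"],
                          "age": age}, index=samples.index)
    table = pd.concat([table, tv], axis=1)
    roc = None
    if "status" in samples.columns and samples["status"].nunique() == 2:
        y = (samples["status"] == "case").to_numpy(float)
        roc = roc_auc(score, y)
    return table, roc


# ---------------------------------------------------------------------------
# synthetic reference cohort with the locked structure as generative truth
# ---------------------------------------------------------------------------

#: per-component generative plan: (driver cell type, CAD shift, sex mode)
_REFERENCE_PLAN = {
    "1a": ("neutrophil", 0.40, "antagonistic"),   # up in men, down in women
    "1b": ("neutrophil", -0.40, "antagonistic"),  # down in men, up in women
    "2a": ("neutrophil", 0.45, "antagonistic"),
    "2b": ("lymphocyte_T", 0.0, "both"),          # RPL28: stable
    "2c": ("neutrophil", 0.0, "both"),            # CAD-insensitive neutrophil
    "3a": ("NK", -0.35, "both"),                  # lymphocyte genes down,
    "3b": ("lymphocyte_T", -0.10, "both"),        # sex-independent
    "4a": ("lymphocyte_B", 0.30, "both"),
    "5a": ("none", 0.30, "both"),
    "5b": ("none", 0.0, "both"),
    "6a": ("none", 0.35, "male_only"),
}


def reference_cohort_config(n_samples: int = 640, seed: int = 17,
                            noise_sd: float = 1.0) -> simulate.SimulationConfig:
    """Simulation config whose planted truth follows the locked structure."""
    structure = locked_term_definitions()
    clusters, effects = [], []
    for code, (driver, shift, mode) in _REFERENCE_PLAN.items():
        clusters.append(simulate.ClusterSpec(code, len(structure.components[code]),
                                             driver, 0.7))
        if shift != 0.0:
            effects.append(simulate.EffectSpec(code, shift, mode))
    return simulate.SimulationConfig(
        n_samples=n_samples, n_genes=23, cluster_spec=clusters,
        effect_spec=effects, noise_sd=noise_sd, seed=seed)


def locked_oracle_auc(n_samples_ignored: int = 0, seed: int = 17,
                      noise_sd: float = 1.0, n_mc: int = 20000) -> float:
    """Generative Bayes AUC of the locked-term observables on the

    reference world: the optimal score restricted to the six sex-resolved
    locked terms plus the age/sex prior, estimated by Monte Carlo (see
    :func:`cadscore.simulate.bayes_auc`).  This is the ceiling a locked
    score with ideal coefficients can reach on the reference cohort."""
    structure = locked_term_definitions()
    config = reference_cohort_config(640, seed, noise_sd)
    placeholder = {code: [f"G_{code}_{j:03d}" for j in range(len(genes))]
                   for code, genes in structure.components.items()
                   if code in _REFERENCE_PLAN}
    # components sharing physical genes with a generated cluster
    placeholder["4b"] = placeholder["3b"]
    placeholder["6b"] = placeholder["5b"]
    gene_ids = [g for code in _REFERENCE_PLAN for g in placeholder[code]]

    def projection(sex: str) -> pd.DataFrame:
        rows = {}
        for tid, spec in structure.term_map.items():
            if spec["sex"] == "male_only" and sex == "F":
                continue
            w = pd.Series(0.0, index=pd.Index(gene_ids).unique())
            for code, sgn in ((spec["num"], 1.0), (spec["den"][sex], -1.0)):
                ids = placeholder[code]
                for g in ids:
                    w[g] += sgn / len(ids)
            rows[tid] = w
        return pd.DataFrame(rows).T

    return simulate.bayes_auc(config, n_mc=n_mc,
                              projection={"M": projection("M"),
                                          "F": projection("F")})


def locked_reference_cohort(n_samples: int = 640, seed: int = 17,
                            noise_sd: float = 1.0):
    """Synthetic cohort whose genes carry the locked 23 symbols.

    Returns (matrix, samples, latent, truth) from
    :func:`cadscore.simulate.generate_cohort`, with genes renamed from the
    per-component placeholders to the real locked symbols.  Component 4b is
    the same physical genes as 3b, so it is not generated twice.
    """
    structure = locked_term_definitions()
    config = reference_cohort_config(n_samples, seed, noise_sd)
    matrix, samples, latent, truth = simulate.generate_cohort(config)
    rename = {}
    for code, (driver, _, _) in _REFERENCE_PLAN.items():
        for j, gene in enumerate(structure.components[code]):
            rename[f"G_{code}_{j:03d}"] = gene
    matrix = ExpressionMatrix(matrix.data.rename(index=rename),
                              scale=matrix.scale, platform=matrix.platform)
    truth = truth.rename(index=rename)
    return matrix, samples, latent, truth
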