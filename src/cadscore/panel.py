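"""RT-PCR panel selection: clustering, cell-type annotation, normalization
genes, and sex-stratified direction summaries.

Also ships the reference 113-gene RT-PCR panel table (gene, co-expression
cluster 1-18, cell-type codes, meta-gene 1-15 / Norm, algorithm-term code)
used by the locked scoring module; the identity of that list was a
judgment call blending statistics, pathway analysis and literature, so it
is packaged as data rather than re-derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ConfigurationError, DataError, ExpressionMatrix


def load_reference_panel() -> pd.DataFrame:
    """The packaged 113-gene RT-PCR panel table, indexed by gene symbol."""
    with resources.files("cadscore.reference").joinpath("table2.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    df = df.set_index("gene")
    df["cluster_id"] = df["cluster"].str.split(".").str[0].astype(int)
    return df


# ---------------------------------------------------------------------------
# correlation clustering
# ---------------------------------------------------------------------------

@dataclass
class GeneCluster:
    """One correlation cluster of genes."""

    cluster_id: int
    genes: list
    medoid: str
    mean_intra_correlation: float


def cluster_genes(matrix: ExpressionMatrix, corr_cutoff: float) -> list:
    """Agglomerative clustering on gene:gene Pearson correlations.

    Distance is ``1 - r`` with average linkage; the tree is cut at height
    ``1 - corr_cutoff``.  Singletons are allowed; constant genes (undefined
    correlation) become their own singletons with a warning.  Output is
    invariant to gene order and to positive affine transforms per gene.
    """
    if not 0.0 < corr_cutoff < 1.0:
        raise ConfigurationError("corr_cutoff must be in (0, 1)")
    if matrix.n_genes < 2:
        raise DataError("need at least 2 genes to cluster")
    vals = matrix.values
    sds = vals.std(axis=1)
    constant = sds == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene(s) assigned to "
                      "singleton clusters", stacklevel=2)
    order = np.argsort(matrix.genes[~constant])  # order-invariance
    genes_ok = matrix.genes[~constant][order]
    clusters: list[GeneCluster] = []
    next_id = 1
    if len(genes_ok) >= 2:
        sub = vals[~constant][order]
        r = np.corrcoef(sub)
        dist = np.clip(1.0 - r, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        tree = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(tree, t=1.0 - corr_cutoff, criterion="distance")
        for lab in np.unique(labels):
            members_idx = np.where(labels == lab)[0]
            members = [genes_ok[i] for i in members_idx]
            rr = r[np.ix_(members_idx, members_idx)]
            if len(members) > 1:
                offdiag = rr[~np.eye(len(members), dtype=bool)]
                mean_r = float(offdiag.mean())
                mean_to_others = (rr.sum(axis=1) - 1.0) / (len(members) - 1)
                medoid = members[int(np.argmax(mean_to_others))]
            else:
                mean_r = 1.0
                medoid = members[0]
            clusters.append(GeneCluster(next_id, sorted(members), medoid, mean_r))
            next_id += 1
    elif len(genes_ok) == 1:
        g = genes_ok[0]
        clusters.append(GeneCluster(next_id, [g], g, 1.0))
        next_id += 1
    for g in sorted(matrix.genes[constant]):
        clusters.append(GeneCluster(next_id, [g], g, 1.0))
        next_id += 1
    return clusters


def cluster_assignments(clusters) -> pd.Series:
    """gene -> cluster id mapping from a list of GeneCluster."""
    out = {}
    for c in clusters:
        for g in c.genes:
            out[g] = c.cluster_id
    return pd.Series(out, name="cluster")


# ---------------------------------------------------------------------------
# cell-type annotation
# ---------------------------------------------------------------------------

CELL_TAGS = ("neutrophil", "lymphocyte", "T cell", "B cell", "NK",
             "eosinophil", "monocyte", "none")
COUNT_TAGS = {"neutrophil_count": "neutrophil", "lymphocyte_count": "lymphocyte"}


def assign_cell_types(matrix: ExpressionMatrix, samples: pd.DataFrame,
                      marker_map: dict | None = None,
                      corr_threshold: float = 0.3) -> pd.DataFrame:
    """Tag genes by correlation with blood counts and/or marker genes.

    A tag is assigned when ``|r| >= corr_threshold`` against the relevant
    count (evidence ``count-correlation``; neutrophil and total-lymphocyte
    counts are available, so count evidence uses the lineage-level tags) or
    against a supplied marker gene mapped to a tag (evidence
    ``marker-correlation``).  The sign of r is recorded.  Genes with no
    evidence get a single ``none`` row.
    """
    marker_map = marker_map or {}
    for tag in marker_map.values():
        if tag not in CELL_TAGS:
            raise ConfigurationError(f"unknown cell-type tag {tag!r}")
    samples = samples.loc[list(matrix.samples)]
    vals = matrix.values
    rows = []
    count_cols = []
    for col, tag in COUNT_TAGS.items():
        if col in samples.columns and samples[col].notna().all():
            count_cols.append((col, tag, samples[col].to_numpy(float)))
        else:
            warnings.warn(f"{col} missing: count-correlation evidence skipped",
                          stacklevel=2)
    marker_vecs = []
    for mg, tag in marker_map.items():
        if mg not in matrix.genes:
            raise DataError(f"marker gene {mg!r} not in matrix")
        marker_vecs.append((mg, tag, matrix.data.loc[mg].to_numpy()))
    for i, gene in enumerate(matrix.genes):
        x = vals[i]
        tagged = False
        if np.std(x) > 0:
            for col, tag, cnt in count_cols:
                r = float(np.corrcoef(x, cnt)[0, 1])
                if abs(r) >= corr_threshold:
                    rows.append((gene, tag, "count-correlation", r))
                    tagged = True
            for mg, tag, mx in marker_vecs:
                if mg == gene or np.std(mx) == 0:
                    continue
                r = float(np.corrcoef(x, mx)[0, 1])
                if abs(r) >= corr_threshold:
                    rows.append((gene, tag, "marker-correlation", r))
                    tagged = True
        if not tagged:
            rows.append((gene, "none", "none", np.nan))
    return pd.DataFrame(rows, columns=["gene", "tag", "evidence", "r"])


# ---------------------------------------------------------------------------
# normalization candidates
# ---------------------------------------------------------------------------

def select_normalization_candidates(matrix: ExpressionMatrix,
                                    samples: pd.DataFrame,
                                    var_quantile_max: float = 0.25,
                                    expr_quantile_range=(0.25, 0.90),
                                    alpha: float = 0.05) -> pd.DataFrame:
    """Candidate normalization genes, ranked by variance ascending.

    A gene qualifies when its variance is at or below the
    ``var_quantile_max`` cohort quantile, its mean expression falls inside
    ``expr_quantile_range`` (moderate-to-high), and it shows *no*
    significant correlation (p >= alpha, Pearson / point-biserial) with
    case:control status, sex, age, or neutrophil/lymphocyte counts.  When
    nothing passes, the returned empty frame carries a ``diagnostic`` attr
    naming the filter that excluded the most genes.
    """
    lo, hi = expr_quantile_range
    if not (0 <= var_quantile_max <= 1 and 0 <= lo < hi <= 1):
        raise ConfigurationError("invalid quantile criteria")
    samples = samples.loc[list(matrix.samples)]
    vals = matrix.values
    variances = vals.var(axis=1, ddof=1)
    means = vals.mean(axis=1)
    var_cut = np.quantile(variances, var_quantile_max)
    mean_lo, mean_hi = np.quantile(means, [lo, hi])

    screens = {
        "status": (samples["status"] == "case").to_numpy(float),
        "sex": (samples["sex"] == "M").to_numpy(float),
        "age": samples["age"].to_numpy(float),
    }
    for col in ("neutrophil_count", "lymphocyte_count"):
        if col in samples.columns and samples[col].notna().all():
            screens[col] = samples[col].to_numpy(float)

    fail_counts = {"variance": 0, "expression": 0, **{k: 0 for k in screens}}
    rows = []
    for i, gene in enumerate(matrix.genes):
        ok = True
        if variances[i] > var_cut:
            fail_counts["variance"] += 1
            ok = False
        if not (mean_lo <= means[i] <= mean_hi):
            fail_counts["expression"] += 1
            ok = False
        min_p = 1.0
        if np.std(vals[i]) > 0:
            for name, cov in screens.items():
                if np.std(cov) == 0:
                    continue
                p = stats.pearsonr(vals[i], cov).pvalue
                min_p = min(min_p, p)
                if p < alpha:
                    fail_counts[name] += 1
                    ok = False
        if ok:
            rows.append((gene, variances[i], means[i], min_p))
    out = pd.DataFrame(rows, columns=["gene", "variance", "mean", "min_screen_p"])
    out = out.sort_values(["variance", "gene"]).set_index("gene")
    if out.empty:
        worst = max(fail_counts, key=fail_counts.get)
        out.attrs["diagnostic"] = (f"no gene passed all filters; most exclusions "
                                   f"by {worst!r} ({fail_counts[worst]} genes)")
        warnings.warn(out.attrs["diagnostic"], stacklevel=2)
    else:
        out.attrs["diagnostic"] = ""
    return out


# ---------------------------------------------------------------------------
# sex-stratified direction
# ---------------------------------------------------------------------------

def sex_stratified_direction(matrix: ExpressionMatrix, samples: pd.DataFrame,
                             genes=None):
    """Per-sex case-vs-control direction of each gene.

    Returns ``(summary, per_gene)``: the summary counts up/down genes per
    sex (sign of the case-minus-control mean difference); ``per_gene``
    carries the differences and signs.  An absent sex stratum is reported
    as missing (NaN counts) rather than an error.
    """
    samples = samples.loc[list(matrix.samples)]
    if genes is not None:
        matrix = matrix.subset(genes=genes)
    per_gene = pd.DataFrame(index=matrix.genes)
    summary_rows = {}
    for sex in ("M", "F"):
        mask = (samples["sex"] == sex).to_numpy()
        case = mask & (samples["status"] == "case").to_numpy()
        ctrl = mask & (samples["status"] == "control").to_numpy()
        if case.sum() == 0 or ctrl.sum() == 0:
            per_gene[f"diff_{sex}"] = np.nan
            per_gene[f"sign_{sex}"] = np.nan
            summary_rows[sex] = {"n_up": np.nan, "n_down": np.nan,
                                 "missing": True}
            continue
        diff = matrix.values[:, case].mean(axis=1) - matrix.values[:, ctrl].mean(axis=1)
        per_gene[f"diff_{sex}"] = diff
        per_gene[f"sign_{sex}"] = np.sign(diff)
        summary_rows[sex] = {"n_up": int((diff > 0).sum()),
                             "n_down": int((diff < 0).sum()),
                             "missing": False}
    summary = pd.DataFrame(summary_rows).T
    summary.index.name = "sex"
    return summary, per_gene


# ---------------------------------------------------------------------------
# panel selection
# ---------------------------------------------------------------------------

def select_panel(assoc: pd.DataFrame, clusters, priority_flags=None,
                 panel_size: int = 113, alpha: float = 0.05,
                 p_column: str = "p_unadjusted") -> list:
    """Greedy RT-PCR panel selection with cluster representation.

    First the smallest-p gene of every cluster holding at least one
    significant gene (``p < alpha``) enters, in order of that best p; then
    remaining slots fill by priority flag (e.g. literature support), then by
    p, then lexicographically by gene id (the deterministic tie-break).
    A ``panel_size`` below the number of represented clusters truncates the
    cluster representatives by best-gene p, with a warning.
    """
    priority_flags = priority_flags or {}
    pvals = assoc[p_column]
    reps = []  # (best_p, gene) per cluster with a significant member
    for c in clusters:
        member_p = pvals.reindex(c.genes).dropna()
        if member_p.empty:
            continue
        best_p = member_p.min()
        best_gene = sorted(member_p.index[member_p == best_p])[0]
        if best_p < alpha:
            reps.append((best_p, best_gene))
    reps.sort(key=lambda t: (t[0], t[1]))
    if panel_size < len(reps):
        warnings.warn(f"panel_size {panel_size} < {len(reps)} represented "
                      "clusters; truncating by best-gene p", stacklevel=2)
    panel = [g for _, g in reps[:panel_size]]
    if len(panel) < panel_size:
        rest = [(0 if priority_flags.get(g) else 1, pvals.get(g, 1.0), g)
                for g in assoc.index if g not in panel]
        rest.sort()
        panel.extend(g for _, _, g in rest[:panel_size - len(panel)])
    return panel
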