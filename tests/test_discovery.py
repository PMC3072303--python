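import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit

from cadscore import ConfigurationError, DataError, discovery
from cadscore.discovery import (QCThresholds, bh_fdr, clinical_factor_association,
                                contingency_chi2, enrich_hypergeometric,
                                gene_association, intersect_discovery,
                                normalize_trimmed_mean, paired_gene_association,
                                qc_samples)

from conftest import make_matrix, make_samples


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestTrimmedMeanNormalization:
    def test_hand_computed_scaling(self):
        # sample (1,2,3,4,1000), 20% trim per tail -> trimmed mean = mean(2,3,4)
        m = make_matrix(np.array([[1.0], [2.0], [3.0], [4.0], [1000.0]]),
                        scale="linear")
        out = normalize_trimmed_mean(m, target=100.0, trim_fraction=0.2,
                                     log_offset=0.0)
        scale = 100.0 / 3.0
        expected = np.log2(np.array([1, 2, 3, 4, 1000.0]) * scale)
        np.testing.assert_allclose(out.values[:, 0], expected, rtol=1e-12)

    def test_sample_already_at_target_is_log2_identity(self):
        vals = np.array([[80.0], [100.0], [120.0]])  # mean = 100, no trim
        m = make_matrix(vals, scale="linear")
        out = normalize_trimmed_mean(m, trim_fraction=0.0, log_offset=0.0)
        np.testing.assert_allclose(out.values, np.log2(vals), rtol=1e-12)

    def test_invariant_to_positive_rescaling_per_sample(self, rng):
        vals = rng.uniform(1, 500, size=(30, 3))
        m1 = make_matrix(vals, scale="linear")
        scaled = vals.copy()
        scaled[:, 1] *= 10.0  # rescale one sample
        m2 = make_matrix(scaled, scale="linear")
        out1 = normalize_trimmed_mean(m1)
        out2 = normalize_trimmed_mean(m2)
        np.testing.assert_allclose(out1.values, out2.values, rtol=1e-10)

    def test_all_zero_sample_error_names_sample(self):
        m = make_matrix(np.array([[1.0, 0.0], [2.0, 0.0]]), scale="linear",
                        samples=["good", "dead"])
        with pytest.raises(DataError, match="dead"):
            normalize_trimmed_mean(m)

    def test_rejects_log_scale_input_and_bad_trim(self, rng):
        lin = make_matrix(rng.uniform(1, 10, (4, 2)), scale="linear")
        with pytest.raises(ConfigurationError):
            normalize_trimmed_mean(lin, trim_fraction=0.5)
        with pytest.raises(ConfigurationError):
            normalize_trimmed_mean(make_matrix(rng.normal(size=(4, 2))))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

class TestQC:
    def test_identical_samples_pass_with_unit_correlation(self, rng):
        col = rng.uniform(2, 10, size=50)
        m = make_matrix(np.column_stack([col, col]))
        rep = qc_samples(m)
        assert rep.all_passed
        np.testing.assert_allclose(rep.metrics["median_correlation"], 1.0)

    def test_zero_detection_fails_percent_present(self, rng):
        vals = rng.uniform(5, 10, size=(40, 3))
        vals[:, 2] = 0.0  # nothing above the detection threshold
        rep = qc_samples(make_matrix(vals))
        assert "s2" in rep.excluded
        assert not rep.metrics.loc["s2", "pass_percent_present"]

    def test_decorrelated_sample_is_the_only_correlation_failure(self, rng):
        # 9 samples share a strong latent profile; the 10th is independent
        latent = rng.normal(0, 2, size=200)
        cols = [latent + rng.normal(0, 0.5, 200) + 8 for _ in range(9)]
        cols.append(rng.normal(8, 2, size=200))
        rep = qc_samples(make_matrix(np.column_stack(cols)),
                         QCThresholds(correlation_min=0.5,
                                      intensity_mad_max=100))
        assert list(rep.excluded) == ["s9"]

    def test_single_sample_reports_missing_correlation(self, rng):
        with pytest.warns(UserWarning, match="single sample"):
            rep = qc_samples(make_matrix(rng.uniform(4, 10, (30, 1))))
        assert np.isnan(rep.metrics["median_correlation"]).all()
        assert rep.all_passed


# ---------------------------------------------------------------------------
# unpaired association
# ---------------------------------------------------------------------------

def _profile_ml_beta(x, y):
    """Independent 2-parameter ML oracle: profile the intercept out with a

    1-d root solve, then maximise the profile likelihood over beta."""
    def b0_for(beta):
        return brentq(lambda b0: expit(b0 + beta * x).mean() - y.mean(),
                      -50, 50)

    def negloglik(beta):
        eta = b0_for(beta) + beta * x
        return -(y * eta - np.log1p(np.exp(eta))).sum()

    res = minimize_scalar(negloglik, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-10})
    return res.x


class TestGeneAssociation:
    def test_matches_profile_likelihood_oracle(self, rng):
        x = rng.normal(size=40)
        y = (rng.random(40) < expit(0.8 * x - 0.3)).astype(float)
        m = make_matrix(x[None, :])
        s = make_samples(["case" if v else "control" for v in y])
        res = gene_association(m, s)
        beta_oracle = _profile_ml_beta(x, y)
        assert abs(res["beta"].iloc[0] - beta_oracle) < 1e-6

    def test_constant_gene_is_degenerate(self, rng):
        m = make_matrix(np.vstack([np.full(20, 5.0), rng.normal(size=20)]))
        s = make_samples(["case"] * 10 + ["control"] * 10)
        res = gene_association(m, s)
        assert res.loc["g0", "flag"] == "degenerate"
        assert res.loc["g0", "beta"] == 0.0
        assert res.loc["g0", "p_unadjusted"] == 1.0

    def test_complete_separation_flagged_with_finite_beta(self):
        x = np.array([1.0] * 10 + [-1.0] * 10) + np.arange(20) * 1e-4
        m = make_matrix(x[None, :])
        s = make_samples(["case"] * 10 + ["control"] * 10)
        res = gene_association(m, s)
        assert res["flag"].iloc[0] == "separated"
        assert np.isfinite(res["beta"].iloc[0])
        assert res["p_unadjusted"].iloc[0] < 0.05

    def test_single_class_rejected(self, rng):
        m = make_matrix(rng.normal(size=(2, 10)))
        s = make_samples(["case"] * 10)
        with pytest.raises(DataError, match="both cases and controls"):
            gene_association(m, s)

    def test_id_mismatch_lists_offenders(self, rng):
        m = make_matrix(rng.normal(size=(2, 4)))
        s = make_samples(["case", "control", "case"])
        with pytest.raises(DataError, match="s3"):
            gene_association(m, s)

    def test_adjusted_fit_adds_sex_age_covariates(self, rng):
        n = 120
        age = rng.uniform(40, 80, n)
        y = (rng.random(n) < expit(0.08 * (age - 60))).astype(float)
        x = rng.normal(size=n) + 0.5 * (age - 60) / 10  # age-confounded gene
        m = make_matrix(x[None, :])
        s = make_samples(["case" if v else "control" for v in y],
                         sex=list(rng.choice(["M", "F"], n)), age=list(age))
        unadj = gene_association(m, s)["beta"].iloc[0]
        adj = gene_association(m, s, adjust="sex_age")["p_adjusted"].iloc[0]
        # confounded effect should weaken after adjustment
        oracle = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert abs(unadj - oracle.params[1]) < 1e-6
        assert adj > oracle.pvalues[1]

    def test_robust_fit_downweights_gross_outlier(self, rng):
        n = 80
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(1.0 * x)).astype(float)
        x_dirty = x.copy()
        # residual outlier: a control with wildly high expression drags the
        # plain ML slope down; the Huber weights should resist it
        x_dirty[0] = 6.0
        y[0] = 0.0
        s = make_samples(["case" if v else "control" for v in y])
        clean = gene_association(make_matrix(x[None, :]), s)["beta"].iloc[0]
        plain = gene_association(make_matrix(x_dirty[None, :]), s)["beta"].iloc[0]
        robust = gene_association(make_matrix(x_dirty[None, :]), s,
                                  robust=True)["beta"].iloc[0]
        assert plain < clean  # the outlier attenuates the plain fit
        assert abs(robust - clean) < abs(plain - clean)


# ---------------------------------------------------------------------------
# paired (conditional) association
# ---------------------------------------------------------------------------

def _paired_fixture(rng, n_pairs=20, beta=0.7):
    d = rng.normal(0.2, 1.0, size=n_pairs)
    # conditional likelihood density: pair is (case, control) with diff d
    ids, status, pair_ids, values = [], [], [], []
    for i, di in enumerate(d):
        base = rng.normal(8, 1)
        ids += [f"c{i}", f"t{i}"]
        status += ["case", "control"]
        pair_ids += [f"P{i}", f"P{i}"]
        values += [base + di, base]
    s = pd.DataFrame({"status": status, "sex": "M", "age": 60.0,
                      "pair_id": pair_ids},
                     index=pd.Index(ids, name="sample_id"))
    from cadscore import validate_samples
    m = make_matrix(np.array(values)[None, :], samples=ids)
    return m, validate_samples(s), np.asarray(d)


class TestPairedAssociation:
    def test_zero_differences_give_null_result(self):
        ids = [f"x{i}" for i in range(8)]
        s = pd.DataFrame({"status": ["case", "control"] * 4, "sex": "M",
                          "age": 60.0,
                          "pair_id": np.repeat([f"P{i}" for i in range(4)], 2)},
                         index=pd.Index(ids, name="sample_id"))
        from cadscore import validate_samples
        m = make_matrix(np.full((1, 8), 7.0), samples=ids)
        res = paired_gene_association(m, validate_samples(s))
        assert res["beta"].iloc[0] == 0.0
        assert res["p_unadjusted"].iloc[0] == 1.0
        assert res["flag"].iloc[0] == "degenerate"

    def test_beta_matches_grid_oracle_of_stated_likelihood(self, rng):
        m, s, d = _paired_fixture(rng)

        def negloglik(beta):  # L = prod 1/(1+exp(-beta d_i))
            return np.log1p(np.exp(-beta * d)).sum()

        oracle = minimize_scalar(negloglik, bounds=(-20, 20), method="bounded",
                                 options={"xatol": 1e-11}).x
        res = paired_gene_association(m, s)
        assert abs(res["beta"].iloc[0] - oracle) < 1e-6

    def test_equivalence_with_intercept_free_logistic_on_differences(self, rng):
        m, s, d = _paired_fixture(rng, n_pairs=30)
        # flip half the differences and label them 0: identical likelihood,
        # avoids a single-class outcome for the statsmodels route
        y = np.array([1.0] * 15 + [0.0] * 15)
        x = np.where(y == 1, d, -d)
        sm_beta = sm.Logit(y, x[:, None]).fit(disp=0).params[0]
        res = paired_gene_association(m, s)
        assert abs(res["beta"].iloc[0] - sm_beta) < 1e-8

    def test_one_signed_differences_flagged_separated(self, rng):
        m, s, d = _paired_fixture(rng)
        m2 = make_matrix(np.abs(m.values - m.values.min()) + 1,
                         samples=list(m.samples))
        # force case > control in every pair
        vals = m2.data.copy()
        for i in range(20):
            vals.loc["g0", f"c{i}"] = vals.loc["g0", f"t{i}"] + 1.0
        res = paired_gene_association(
            make_matrix(vals.to_numpy(), samples=list(vals.columns)), s)
        assert res["flag"].iloc[0] == "separated"
        assert np.isfinite(res["beta"].iloc[0])

    def test_malformed_pair_rejected(self, rng):
        m, s, _ = _paired_fixture(rng, n_pairs=4)
        s2 = s.copy()
        s2.loc["t0", "status"] = "case"  # two cases in P0
        with pytest.raises(DataError, match="P0"):
            paired_gene_association(m, s2)


# ---------------------------------------------------------------------------
# multiplicity / intersection / enrichment
# ---------------------------------------------------------------------------

class TestBhFdr:
    def test_worked_examples(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_direct_step_up_formula(self):
        p = np.array([0.001, 0.2, 0.8, 0.04])
        order = np.argsort(p)
        q_sorted = p[order] * len(p) / (np.arange(len(p)) + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty_like(p)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_fdr(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(DataError):
            bh_fdr([-0.1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_monotone_and_permutation_invariant(self, p):
        p = np.asarray(p)
        q = bh_fdr(p)
        # q is monotone in p when both are sorted
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        # permuting input permutes output identically
        perm = np.random.RandomState(0).permutation(len(p))
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])


class TestIntersection:
    def test_disjoint_and_identical_sets(self, rng):
        a = pd.DataFrame({"p_unadjusted": [0.01, 0.8]}, index=["g1", "g2"])
        b = pd.DataFrame({"p_unadjusted": [0.9, 0.01]}, index=["g1", "g2"])
        assert intersect_discovery(a, b) == set()
        assert intersect_discovery(a, a) == {"g1"}

    def test_intersection_enriched_for_planted_genes(self):
        from cadscore.simulate import (ClusterSpec, EffectSpec,
                                       SimulationConfig, generate_cohort)
        sig_sets = []
        for seed in (1, 2):
            cfg = SimulationConfig(
                n_samples=400, n_genes=60, seed=seed,
                cluster_spec=[ClusterSpec("hit", 15, "none")],
                effect_spec=[EffectSpec("hit", 0.6, "both")])
            matrix, samples, _, truth = generate_cohort(cfg)
            sig_sets.append(gene_association(matrix, samples))
        inter = intersect_discovery(sig_sets[0], sig_sets[1])
        planted = set(truth.index[truth["shift_male"] != 0])
        frac_planted_in = len(inter & planted) / len(planted)
        frac_null_in = len(inter - planted) / (60 - len(planted))
        assert frac_planted_in > 0.8 > frac_null_in


class TestHypergeometricEnrichment:
    def test_exact_enumeration_oracle(self):
        universe = [f"u{i}" for i in range(20)]
        term = set(universe[:4])
        study = set(universe[:3]) | {universe[10], universe[11]}  # overlap 3
        res = enrich_hypergeometric(study, {"T": term}, universe)
        count = 0
        total = 0
        for draw in itertools.combinations(universe, 5):
            total += 1
            if len(set(draw) & term) >= 3:
                count += 1
        assert res.loc["T", "p"] == pytest.approx(count / total, rel=1e-12)

    def test_degenerate_overlaps(self):
        universe = [f"u{i}" for i in range(10)]
        study = set(universe[:4])
        res = enrich_hypergeometric(study,
                                    {"none": set(universe[6:]),
                                     "all": set(universe)}, universe)
        assert res.loc["none", "p"] <= 1.0  # P[X >= 0] only when overlap 0
        assert res.loc["all", "overlap"] == 4
        assert res.loc["all", "p"] == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one(self):
        universe = list("abcdefgh")
        res = enrich_hypergeometric({"a", "b"}, {"T": {"g", "h"}}, universe)
        assert res.loc["T", "p"] == pytest.approx(1.0)

    def test_empty_universe_and_stray_study_rejected(self):
        with pytest.raises(DataError):
            enrich_hypergeometric(set(), {}, set())
        with pytest.raises(DataError, match="outside universe"):
            enrich_hypergeometric({"x"}, {}, {"a"})


# ---------------------------------------------------------------------------
# clinical factors
# ---------------------------------------------------------------------------

class TestClinicalFactors:
    def test_chest_pain_contingency_reproduces_published_p(self):
        # controls 141/56/137/65 vs cases 90/29/47/61 across the four
        # chest-pain categories; published p printed as .0004
        table = [[141, 90], [56, 29], [137, 47], [65, 61]]
        stat, p, dof = contingency_chi2(table)
        assert dof == 3
        assert 2e-4 <= p <= 8e-4

    def test_two_by_two_matches_hand_formula(self):
        table = np.array([[10, 20], [20, 10.0]])
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        stat_hand = ((table - exp) ** 2 / exp).sum()
        stat, p, dof = contingency_chi2(table)
        assert stat == pytest.approx(stat_hand, rel=1e-12)
        assert dof == 1

    def test_identical_categorical_distribution_gives_p_one(self):
        s = make_samples(["case"] * 40 + ["control"] * 40,
                         chest_pain=(["typical"] * 20 + ["atypical"] * 20) * 2)
        res = clinical_factor_association(s, factors=["chest_pain"])
        assert res.loc["chest_pain", "p"] == pytest.approx(1.0)

    def test_continuous_factor_and_multivariate(self, rng):
        n = 200
        age = rng.uniform(40, 80, n)
        y = rng.random(n) < expit(0.08 * (age - 60))
        s = make_samples(["case" if v else "control" for v in y],
                         age=list(age), sex=list(rng.choice(["M", "F"], n)),
                         neutrophil_count=list(rng.uniform(2, 6, n)))
        res = clinical_factor_association(
            s, factors=["age", "neutrophil_count"],
            multivariate=["age", "neutrophil_count"])
        assert res.loc["age", "p"] < 0.01
        assert res.loc["neutrophil_count", "p"] > 0.01
        assert res.loc["age", "p_multivariate"] < 0.01

    def test_zero_variance_factor_flagged(self):
        s = make_samples(["case"] * 5 + ["control"] * 5,
                         neutrophil_count=[4.0] * 10)
        res = clinical_factor_association(s, factors=["neutrophil_count"])
        assert res.loc["neutrophil_count", "kind"] == "degenerate"
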