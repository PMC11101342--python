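import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutlink.assoc import (bh_fdr, feature_screen, impute_covariates,
                           interaction_model, pool_rubin,
                           pooled_reverse_regression, prevalence, pseudocount,
                           reverse_regression)
from gutlink.profiles import AbundanceTable


def brute_force_bh(p):
    """Literal step-up definition: q_(i) = min_{j>=i} m*p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBhFdr:
    def test_constant_vector_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_hand_step_up_case(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_matches_literal_definition_and_is_monotone(self, p):
        q = bh_fdr(p)
        np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= np.asarray(p) - 1e-15).all()


def _planted_table(n=150, n_feat=20, slope=1.0, noise=0.1, seed=0,
                   feature="sp0000"):
    """Score-linked feature on the log2 scale; the rest are null."""
    rng = np.random.default_rng(seed)
    score = rng.normal(50, 10, n)
    vals = rng.lognormal(0, 1, (n, n_feat))
    # planted feature: log2-abundance = 4*z(score) + noise, rest null
    z = (score - score.mean()) / score.std()
    vals[:, 0] = 2.0 ** (slope * 4 * z + rng.normal(0, noise, n))
    table = AbundanceTable(pd.DataFrame(
        vals / vals.sum(1, keepdims=True),
        index=[f"S{i}" for i in range(n)],
        columns=[f"sp{j:04d}" for j in range(n_feat)]))
    md = pd.DataFrame({"srs2_tscore": score}, index=table.sample_ids)
    return table, md


class TestFeatureScreen:
    def test_low_prevalence_feature_dropped_and_counted(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(0, 1, (40, 3))
        vals[2:, 2] = 0.0  # present in 5% of samples
        t = AbundanceTable(pd.DataFrame(vals, columns=["a", "b", "c"]))
        md = pd.DataFrame({"srs2_tscore": rng.normal(50, 10, 40)})
        res = feature_screen(t, md, min_prevalence=0.1)
        assert res.n_dropped == 1 and res.dropped == ["c"]
        assert list(res.table.index) == ["a", "b"]

    def test_planted_feature_gets_smallest_q(self):
        table, md = _planted_table()
        res = feature_screen(table, md)
        assert res.table["q"].idxmin() == "sp0000"
        assert res.table.loc["sp0000", "q"] < 0.05

    def test_null_type_i_rate(self):
        rng = np.random.default_rng(9)
        n, n_feat = 60, 2000
        vals = rng.lognormal(0, 1, (n, n_feat))
        t = AbundanceTable(pd.DataFrame(
            vals / vals.sum(1, keepdims=True),
            columns=[f"f{j}" for j in range(n_feat)]))
        md = pd.DataFrame({"srs2_tscore": rng.normal(50, 10, n)})
        res = feature_screen(t, md)
        frac = (res.table["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_screen_p_equals_reverse_p_without_covariates(self):
        # simple-regression symmetry of the t-test
        table, md = _planted_table(n=80, noise=3.0)
        pc = pseudocount(table)
        scr = feature_screen(table, md)
        for f in ["sp0000", "sp0005"]:
            rev = reverse_regression(table.data[f], md, pc=pc)
            assert scr.table.loc[f, "p"] == pytest.approx(
                rev.coef("log2_abundance").p, rel=1e-9)


class TestReverseRegression:
    def test_recovers_effect_at_reported_scale(self):
        rng = np.random.default_rng(3)
        n = 300
        la = rng.normal(-10, 3, n)
        cov = rng.binomial(1, 0.5, n).astype(float)
        score = 43.6 + 0.41 * la + 2.0 * cov + rng.normal(0, 1.0, n)
        md = pd.DataFrame({"srs2_tscore": score, "cov": cov})
        feat = pd.Series(2.0 ** la)
        res = reverse_regression(feat, md, ["cov"], pc=0.0)
        assert 0.31 <= res.coef("log2_abundance").beta <= 0.51

    def test_null_coverage(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(200):
            feat = pd.Series(rng.lognormal(-8, 2, 100))
            md = pd.DataFrame({"srs2_tscore": rng.normal(50, 10, 100)})
            c = reverse_regression(feat, md).coef("log2_abundance")
            hits += c.ci_low <= 0 <= c.ci_high
        assert 0.90 <= hits / 200 <= 0.985

    def test_scale_invariance_of_log_transform(self):
        rng = np.random.default_rng(5)
        feat = pd.Series(rng.lognormal(-5, 1, 80))
        md = pd.DataFrame({"srs2_tscore": rng.normal(50, 10, 80)})
        b1 = reverse_regression(feat, md, pc=1e-6).coef("log2_abundance").beta
        b2 = reverse_regression(2 * feat, md, pc=2e-6).coef("log2_abundance").beta
        assert b1 == pytest.approx(b2, rel=1e-10)

    def test_constant_feature_rejected(self):
        md = pd.DataFrame({"srs2_tscore": np.arange(20.0)})
        with pytest.raises(ValueError, match="constant"):
            reverse_regression(pd.Series(np.ones(20)), md)


class TestInteractionModel:
    def _sex_data(self, n, male_slope, female_slope, seed, noise=1.0):
        rng = np.random.default_rng(seed)
        sex = rng.binomial(1, 0.5, n).astype(float)
        la = rng.normal(-8, 3, n)
        score = 50 + np.where(sex == 1, male_slope, female_slope) * la \
            + rng.normal(0, noise, n)
        md = pd.DataFrame({"srs2_tscore": score, "sex_male": sex})
        return pd.Series(2.0 ** la), md

    def test_power_and_sign_recovery_at_reported_effects(self):
        detected = 0
        for seed in range(50):
            feat, md = self._sex_data(300, 0.3, -0.2, seed, noise=2.0)
            res = interaction_model(feat, md, pc=0.0)
            ok = res["p_interaction"] < 0.05
            ok &= res["stratified"]["male"].coef("log2_abundance").beta > 0
            ok &= res["stratified"]["female"].coef("log2_abundance").beta < 0
            detected += ok
        assert detected >= 40

    def test_null_interaction_p_uniform(self):
        from scipy.stats import kstest
        ps = []
        for seed in range(200):
            feat, md = self._sex_data(80, 0.2, 0.2, seed + 1000, noise=3.0)
            ps.append(interaction_model(feat, md, pc=0.0)["p_interaction"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_stratified_fit_equals_subset_fit(self):
        feat, md = self._sex_data(120, 0.3, -0.1, 7)
        res = interaction_model(feat, md, pc=1e-9)
        male = md["sex_male"] == 1
        direct = reverse_regression(feat[male.values], md.loc[male.values],
                                    pc=1e-9)
        got = res["stratified"]["male"].terms["beta"]
        np.testing.assert_allclose(got.values, direct.terms["beta"].values,
                                   atol=1e-10)

    def test_single_sex_rejected(self):
        feat, md = self._sex_data(60, 0.3, 0.3, 8)
        md["sex_male"] = 1.0
        with pytest.raises(ValueError, match="per sex"):
            interaction_model(feat, md)


class TestImputation:
    def _md(self, n=200, miss=0.2, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(30, 5, n)
        b = rng.binomial(1, 0.5, n).astype(float)
        y = rng.normal(39, 1.7, n)
        df = pd.DataFrame({"maternal_age": x, "parous": b, "gestational_age": y})
        if miss:
            df.loc[rng.random(n) < miss, "parous"] = np.nan
            df.loc[rng.random(n) < miss / 2, "maternal_age"] = np.nan
        return df

    def test_no_missing_is_identity(self):
        md = self._md(miss=0.0)
        imp = impute_covariates(md, ["maternal_age", "parous", "gestational_age"],
                                m=3, seed=1)
        for c in imp.copies:
            pd.testing.assert_frame_equal(c, md)

    def test_deterministic_given_seed(self):
        md = self._md()
        covs = ["maternal_age", "parous", "gestational_age"]
        a = impute_covariates(md, covs, m=5, seed=42)
        b = impute_covariates(md, covs, m=5, seed=42)
        for x, y in zip(a.copies, b.copies):
            pd.testing.assert_frame_equal(x, y)

    def test_observed_cells_identical_across_copies(self):
        md = self._md()
        covs = ["maternal_age", "parous", "gestational_age"]
        imp = impute_covariates(md, covs, m=4, seed=3)
        obs = md["parous"].notna()
        for c in imp.copies[1:]:
            assert (c.loc[obs, "parous"] == imp.copies[0].loc[obs, "parous"]).all()
            assert not c["parous"].isna().any()

    def test_mcar_binary_mean_recovered(self):
        md = self._md(n=500, miss=0.2, seed=5)
        covs = ["maternal_age", "parous", "gestational_age"]
        imp = impute_covariates(md, covs, m=10, seed=6)
        pooled_mean = np.mean([c["parous"].mean() for c in imp.copies])
        assert pooled_mean == pytest.approx(0.5, abs=0.08)

    def test_fully_missing_covariate_rejected(self):
        md = self._md()
        md["parous"] = np.nan
        with pytest.raises(ValueError, match="100% missing"):
            impute_covariates(md, ["maternal_age", "parous"], m=2, seed=0)


class TestRubinPooling:
    def test_single_imputation_degenerate(self):
        res = pool_rubin([[1.5]], [[0.25]])
        assert res.terms["beta"].iloc[0] == 1.5
        assert res.terms["total_var"].iloc[0] == 0.25

    def test_identical_copies_have_zero_between_variance(self):
        res = pool_rubin([[2.0], [2.0], [2.0]], [[0.3], [0.3], [0.3]])
        assert res.terms["between_var"].iloc[0] == 0.0
        assert res.terms["total_var"].iloc[0] == pytest.approx(0.3)

    def test_hand_case(self):
        res = pool_rubin([[1.0], [2.0]], [[0.5], [0.5]])
        assert res.terms["beta"].iloc[0] == pytest.approx(1.5)
        assert res.terms["between_var"].iloc[0] == pytest.approx(0.5)
        assert res.terms["total_var"].iloc[0] == pytest.approx(1.25)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pool_rubin([[1.0, 2.0]], [[0.5]])

    def test_pooled_equals_complete_case_when_nothing_missing(self):
        rng = np.random.default_rng(11)
        n = 100
        md = pd.DataFrame({
            "srs2_tscore": rng.normal(50, 10, n),
            "maternal_age": rng.normal(30, 5, n),
            "parous": rng.binomial(1, 0.5, n).astype(float)})
        feat = pd.Series(rng.lognormal(-6, 2, n))
        covs = ["maternal_age", "parous"]
        imp = impute_covariates(md, covs, m=3, seed=0)
        pooled = pooled_reverse_regression(feat, imp, covs)
        direct = reverse_regression(feat, md, covs)
        np.testing.assert_allclose(pooled.terms["beta"].values,
                                   direct.terms["beta"].values, atol=1e-10)
        assert (pooled.terms["between_var"] == 0).all()


class TestHelpers:
    def test_pseudocount_is_half_min_nonzero(self):
        t = AbundanceTable(pd.DataFrame([[0.0, 0.2], [0.05, 0.75]]))
        assert pseudocount(t) == 0.025

    def test_prevalence_fraction(self):
        t = AbundanceTable(pd.DataFrame([[0.0, 1.0], [1.0, 1.0]],
                                        columns=["a", "b"]))
        assert prevalence(t)["a"] == 0.5 and prevalence(t)["b"] == 1.0
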