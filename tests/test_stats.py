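"""Statistical battery against definition-based oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from perilesion.stats import (ancova, anova_tukey, bh_fdr, cohens_d,
                              fdr_by_family, impute_mode, tract_regression,
                              two_group_test)


def oracle_anova_f(groups):
    """Hand-computed between/within mean squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def oracle_bh(p):
    """Literal step-up definition: q_i = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


class TestAnovaTukey:
    def test_identical_groups_give_f_zero_p_one(self):
        res = anova_tukey({"a": [1, 1, 1], "b": [1, 1, 1], "c": [1, 1, 1]})
        assert res.f_stat == 0.0 and res.p_value == 1.0
        assert (res.tukey["p_adj"] == 1.0).all()

    def test_f_matches_hand_computation(self):
        groups = [np.array([6.0, 8.0, 4.0, 5.0, 3.0, 4.0]),
                  np.array([8.0, 12.0, 9.0, 11.0, 6.0, 8.0]),
                  np.array([13.0, 9.0, 11.0, 8.0, 7.0, 12.0])]
        res = anova_tukey(groups)
        assert res.f_stat == pytest.approx(oracle_anova_f(groups), abs=1e-6)

    def test_two_groups_rejected_toward_t_test(self):
        with pytest.raises(ValueError, match="two_group_test"):
            anova_tukey({"a": [1, 2], "b": [3, 4]})

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_tukey({"a": [1.0], "b": [1, 2], "c": [3, 4]})

    def test_tukey_adjusted_p_not_below_pairwise_t(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(m, 1.0, 12)
                  for k, m in [("a", 0.0), ("b", 0.5), ("c", 1.0)]}
        res = anova_tukey(groups)
        for _, row in res.tukey.iterrows():
            a, b = groups[row["group_a"]], groups[row["group_b"]]
            _, p_raw = sps.ttest_ind(a, b, equal_var=True)
            assert row["p_adj"] >= p_raw - 1e-9


class TestAncova:
    def test_null_covariate_matches_plain_anova(self):
        rng = np.random.default_rng(8)
        y = np.concatenate([rng.normal(0, 1, 30), rng.normal(0.8, 1, 30)])
        g = ["a"] * 30 + ["b"] * 30
        cov = {"junk": rng.normal(0, 1, 60)}          # no effect, balanced
        p_ancova, _ = ancova(y, g, cov)
        _, p_anova = sps.f_oneway(y[:30], y[30:])
        assert p_ancova == pytest.approx(p_anova, abs=0.05)

    def test_identical_outcome_gives_p_one(self):
        y = np.ones(20)
        g = ["a"] * 10 + ["b"] * 10
        p, _ = ancova(y, g, {"c": np.arange(20.0)})
        assert p == pytest.approx(1.0)

    def test_constant_group_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ancova(np.arange(10.0), ["a"] * 10, {"c": np.arange(10.0)})

    def test_collinear_covariates_named(self):
        y = np.arange(12.0)
        g = ["a", "b"] * 6
        x = np.arange(12.0)
        with pytest.raises(ValueError, match="x1.*x2|x2.*x1"):
            ancova(y, g, {"x1": x, "x2": 2 * x})

    def test_missing_covariates_rejected(self):
        y = np.arange(6.0)
        g = ["a", "b"] * 3
        with pytest.raises(ValueError, match="impute"):
            ancova(y, g, {"c": [1, 2, np.nan, 4, 5, 6]})

    def test_adjusts_for_confounded_covariate(self):
        """A group difference fully explained by the covariate vanishes."""
        rng = np.random.default_rng(9)
        cov = np.concatenate([rng.normal(0, 1, 40), rng.normal(2, 1, 40)])
        y = 1.5 * cov + rng.normal(0, 0.3, 80)
        g = ["a"] * 40 + ["b"] * 40
        _, p_anova = sps.f_oneway(y[:40], y[40:])
        p_ancova, _ = ancova(y, g, {"cov": cov})
        assert p_anova < 0.001 and p_ancova > 0.05


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1, 2, 3], [2, 1, 3]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # pooled SD = sqrt(2), difference -2 -> d = -sqrt(2)
        assert cohens_d([0, 2], [2, 4]) == pytest.approx(-np.sqrt(2))

    def test_control_minus_patient_orientation(self):
        controls, patients = [0.50, 0.52, 0.48], [0.40, 0.42, 0.38]
        assert cohens_d(controls, patients) > 0   # lower patient FA_T -> d > 0

    def test_zero_pooled_sd_flagged(self):
        with pytest.warns(UserWarning, match="pooled SD"):
            assert np.isnan(cohens_d([1, 1], [1, 1]))

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            cohens_d([1], [1, 2])


class TestTractRegression:
    def test_noiseless_linear_gives_adjusted_r2_one(self):
        x = np.linspace(0, 1, 20)
        res = tract_regression(2.0 * x - 1.0, x)
        assert res.adjusted_r2 == pytest.approx(1.0, abs=1e-10)
        assert res.slope == pytest.approx(2.0, abs=1e-10)

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(11)
        n = 50
        x = rng.normal(0, 1, n)
        cov = pd.DataFrame({"lesion_volume_mL": rng.normal(2, 1, n),
                            "depression": rng.binomial(1, 0.2, n).astype(float)})
        y = 0.7 * x - 0.3 * cov["lesion_volume_mL"] + rng.normal(0, 0.5, n)
        res = tract_regression(y, x, cov)
        X = np.column_stack([np.ones(n), x, cov["lesion_volume_mL"],
                             cov["depression"]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.slope == pytest.approx(beta[1], abs=1e-8)
        # adjusted R^2 from its definition
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        adj = 1 - (1 - r2) * (n - 1) / (n - 3 - 1)
        assert res.adjusted_r2 == pytest.approx(adj, abs=1e-8)

    def test_slope_recovered_from_simulated_cohort(self):
        from perilesion.phantom import generate_cohort_table
        rng = np.random.default_rng(13)
        metric = rng.normal(0.0, 1.0, 200)
        tab = generate_cohort_table(200, {"language": (1.0, 0.5)}, seed=13,
                                    tract_metric=metric)
        res = tract_regression(tab["language"],
                               tab["FA_T"] - tab["FA_T"].mean())
        # SE(slope) ~ 0.5 / sqrt(200) ~ 0.035; 3 SE margin
        assert res.slope == pytest.approx(1.0, abs=0.11)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            tract_regression([1.0, 2.0], [1.0, 2.0])


class TestBhFdr:
    def test_equal_ps_map_to_themselves(self):
        q = bh_fdr([0.01] * 10)
        np.testing.assert_allclose(q, 0.01)

    def test_matches_definition_oracle(self):
        p = np.array([0.001, 0.01, 0.02, 0.9])
        np.testing.assert_allclose(bh_fdr(p), oracle_bh(p), atol=1e-12)

    def test_random_ps_match_oracle_and_dominate_p(self):
        rng = np.random.default_rng(2)
        p = rng.random(37)
        q = bh_fdr(p)
        np.testing.assert_allclose(q, oracle_bh(p), atol=1e-12)
        assert np.all(q >= p - 1e-12)
        assert np.all((q >= 0) & (q <= 1))

    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_families_corrected_independently(self):
        base = pd.DataFrame({
            "family": ["aff"] * 4 + ["unaff"] * 4,
            "p": [0.04, 0.2, 0.5, 0.9, 0.03, 0.3, 0.6, 0.8]})
        q0 = fdr_by_family(base)["q"]
        spiked = base.copy()
        spiked.loc[0, "p"] = 1e-9               # only the affected family
        q1 = fdr_by_family(spiked)["q"]
        unaff = base["family"] == "unaff"
        np.testing.assert_allclose(q0[unaff], q1[unaff])
        assert q1[0] < q0[0]


class TestImputeMode:
    def test_fills_with_most_frequent(self):
        out = impute_mode(pd.Series([0.0, 0.0, 1.0, np.nan]))
        assert out.tolist() == [0.0, 0.0, 1.0, 0.0]

    def test_no_missing_unchanged(self):
        s = pd.Series([1.0, 0.0, 1.0])
        assert impute_mode(s).tolist() == s.tolist()

    def test_tie_breaks_to_lower_code_with_warning(self):
        with pytest.warns(UserWarning, match="tie"):
            out = impute_mode(pd.Series([0.0, 1.0, np.nan]))
        assert out.iloc[2] == 0.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            impute_mode(pd.Series([np.nan, np.nan]))


class TestNullCalibration:
    def test_family_discovery_rate_near_nominal(self):
        """Under the global null, BH makes >= 1 discovery in ~ alpha of
        families (Simes identity for independent uniform p-values)."""
        rng = np.random.default_rng(19)
        n_rep, m, n = 600, 20, 15
        hits = 0
        for _ in range(n_rep):
            a = rng.standard_normal((m, n))
            b = rng.standard_normal((m, n))
            _, p = sps.ttest_ind(a, b, axis=1)
            hits += (bh_fdr(p) < 0.05).any()
        rate = hits / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 2 * se + 1e-12


def test_welch_default_two_group():
    rng = np.random.default_rng(4)
    a = rng.normal(0, 1, 20)
    b = rng.normal(0, 5, 40)
    t_w, p_w = two_group_test(a, b)
    t_p, p_p = two_group_test(a, b, welch=False)
    assert p_w != p_p
    t_ref, p_ref = sps.ttest_ind(a, b, equal_var=False)
    assert p_w == pytest.approx(p_ref)
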