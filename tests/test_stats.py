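import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from bruteforce import exact_two_group_perm_p
from richclubnet import stats as st


def _random_cohort(rng, n=48):
    return pd.DataFrame({
        "group": rng.choice(["CU", "prodromalAD", "ADdementia"], n),
        "sex": rng.choice(["F", "M"], n),
        "age": rng.normal(70, 8, n),
        "education": rng.normal(12, 4, n),
    })


class TestGlmTermTest:
    def test_hand_anova_eta(self):
        # SS_between = 4, SS_within = 1 -> eta_p2 = 0.8, F = 8
        df = pd.DataFrame({"g": ["a", "a", "b", "b"]})
        res = st.glm_term_test([1, 2, 3, 4], df, "g", covariates=())
        assert res.partial_eta_sq == pytest.approx(0.8)
        assert res.F_statistic == pytest.approx(8.0)

    def test_null_effect_eta_vanishes(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"g": ["a", "b"] * 400})
        res = st.glm_term_test(rng.normal(size=800), df, "g", covariates=())
        assert res.partial_eta_sq < 0.01

    @pytest.mark.parametrize("seed", range(5))
    def test_type3_matches_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        data = _random_cohort(rng)
        y = rng.normal(size=len(data)) + 0.5 * (data.sex == "M")
        d2 = data.assign(y=y)
        fit = smf.ols(
            "y ~ C(group, Sum) * C(sex, Sum) + age + education", d2).fit()
        an = sm.stats.anova_lm(fit, typ=3)
        for term, sm_row in [
            ("group", "C(group, Sum)"),
            ("sex", "C(sex, Sum)"),
            ("group:sex", "C(group, Sum):C(sex, Sum)"),
        ]:
            mine = st.glm_term_test(
                y, data, term, factors=("group", "sex"),
                with_adjusted_means=False)
            # widen to the full interaction model for the main effects too
            if ":" not in term:
                blocks = st._build_design(
                    data, ("group", "sex"), ("age", "education"), True)
                F, *_ = st._term_f(blocks, np.asarray(y), term)
            else:
                F = mine.F_statistic
            assert F == pytest.approx(an.loc[sm_row, "F"], rel=1e-9)

    def test_eta_matches_explicit_projection(self):
        rng = np.random.default_rng(9)
        data = _random_cohort(rng, n=30)
        y = rng.normal(size=30)
        res = st.glm_term_test(y, data, "sex", with_adjusted_means=False)
        # independent route: explicit hat-matrix projections
        blocks = st._build_design(data, ("sex",), ("age", "education"), False)
        X_full = st._stack(blocks)
        X_red = st._stack(blocks, drop="sex")
        P = lambda X: X @ np.linalg.pinv(X.T @ X) @ X.T
        ss_term = y @ (P(X_full) - P(X_red)) @ y
        ss_err = y @ (np.eye(30) - P(X_full)) @ y
        assert res.partial_eta_sq == pytest.approx(
            ss_term / (ss_term + ss_err), rel=1e-9)

    def test_balanced_type3_equals_type1(self):
        rng = np.random.default_rng(4)
        cells = [(g, s) for g in ["CU", "prodromalAD", "ADdementia"]
                 for s in ["F", "M"]]
        data = pd.DataFrame(
            [{"group": g, "sex": s} for g, s in cells for _ in range(8)])
        y = rng.normal(size=len(data))
        d2 = data.assign(y=y)
        fit = smf.ols("y ~ C(group, Sum) * C(sex, Sum)", d2).fit()
        t1 = sm.stats.anova_lm(fit, typ=1)
        blocks = st._build_design(data, ("group", "sex"), (), True)
        for term, row in [("group", "C(group, Sum)"),
                          ("sex", "C(sex, Sum)")]:
            F, *_ = st._term_f(blocks, y, term)
            assert F == pytest.approx(t1.loc[row, "F"], rel=1e-9)

    def test_degenerate_covariate_warns(self):
        rng = np.random.default_rng(1)
        data = _random_cohort(rng, n=20).assign(copy=0.0)
        y = rng.normal(size=20)
        data["copy"] = y
        with pytest.warns(UserWarning, match="degenerate"):
            st.glm_term_test(y, data, "sex", covariates=("copy",),
                             with_adjusted_means=False)

    def test_single_level_factor_rejected(self):
        data = pd.DataFrame({"g": ["a", "a", "a"]})
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            st.glm_term_test([1, 2, 3], data, "g", covariates=())

    def test_adjusted_means_without_covariates_are_cell_means(self):
        df = pd.DataFrame({"g": ["a", "a", "b", "b"]})
        res = st.glm_term_test([1, 2, 3, 4], df, "g", covariates=())
        means = res.adjusted_means.set_index("g")["mean"]
        assert means["a"] == pytest.approx(1.5)
        assert means["b"] == pytest.approx(3.5)


class TestPermutationP:
    def test_exhaustive_matches_enumeration_oracle(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array(["a", "a", "b", "b"])
        df = pd.DataFrame({"g": labels})
        res = st.permutation_adjusted_p(y, df, "g", covariates=(),
                                        exhaustive=True)
        assert res.p_permutation == pytest.approx(
            exact_two_group_perm_p(y, labels))
        assert res.n_perm == 6  # 4!/(2!2!) distinct assignments

    def test_monte_carlo_approaches_exact(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=8)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        df = pd.DataFrame({"g": labels})
        exact = st.permutation_adjusted_p(
            y, df, "g", covariates=(), exhaustive=True).p_permutation
        mc = st.permutation_adjusted_p(
            y, df, "g", covariates=(), n_perm=4000, seed=0).p_permutation
        assert mc == pytest.approx(exact, abs=0.03)

    def test_parametric_agreement_under_gaussian_errors(self):
        rng = np.random.default_rng(8)
        n = 60
        data = pd.DataFrame({
            "sex": np.repeat(["F", "M"], n // 2),
            "age": rng.normal(70, 8, n),
            "education": rng.normal(12, 4, n),
        })
        y = rng.normal(size=n) + 0.45 * (data.sex == "M")
        res = st.permutation_adjusted_p(y, data, "sex", n_perm=3000, seed=1)
        assert res.p_permutation == pytest.approx(res.p_parametric, abs=0.03)

    def test_constant_outcome_p_one(self):
        df = pd.DataFrame({"g": ["a", "a", "b", "b"]})
        with pytest.warns(UserWarning, match="constant outcome"):
            res = st.permutation_adjusted_p(
                np.ones(4), df, "g", covariates=(), n_perm=100, seed=0)
        assert res.p_permutation == 1.0

    def test_lower_bound(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10})
        y = np.r_[rng.normal(0, 1, 10), rng.normal(30, 1, 10)]
        res = st.permutation_adjusted_p(y, df, "g", covariates=(),
                                        n_perm=200, seed=0)
        assert res.p_permutation >= 1 / 201

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        data = _random_cohort(rng, n=36)
        y = rng.normal(size=36)
        a = st.permutation_adjusted_p(y, data, "sex", n_perm=300, seed=7)
        b = st.permutation_adjusted_p(y, data, "sex", n_perm=300, seed=7)
        assert a.p_permutation == b.p_permutation


class TestInteraction:
    def test_empty_cell_rejected(self):
        data = pd.DataFrame({
            "group": ["CU", "CU", "ADdementia", "ADdementia"],
            "sex": ["F", "F", "M", "M"],
            "age": [70.0] * 4, "education": [12.0] * 4,
        })
        with pytest.raises(ValueError, match="empty"):
            st.interaction_test([1, 2, 3, 4], data)

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(6)
        reps = []
        data = pd.DataFrame(
            [{"group": g, "sex": s}
             for g in ["CU", "prodromalAD", "ADdementia"]
             for s in ["F", "M"] for _ in range(15)])
        data["age"] = rng.normal(70, 8, len(data))
        data["education"] = rng.normal(12, 4, len(data))
        effect = ((data.group == "ADdementia") & (data.sex == "F")) * 1.5
        y = rng.normal(size=len(data)) + effect
        res = st.interaction_test(y, data, n_perm=500, seed=0)
        assert res.p_permutation < 0.05


class TestFamilyMaxStat:
    def test_adjusted_p_never_smaller_than_per_outcome(self):
        rng = np.random.default_rng(10)
        data = _random_cohort(rng, n=60)
        outs = {f"o{i}": rng.normal(size=60) for i in range(3)}
        fam = st.family_maxstat_pvalues(outs, data, "sex", n_perm=300, seed=1)
        for name, y in outs.items():
            solo = st.permutation_adjusted_p(
                y, data, "sex", n_perm=300, seed=1)
            assert fam[name].p_permutation >= solo.p_permutation - 1e-12

    def test_groupwise_family_detects_planted_cell(self):
        rng = np.random.default_rng(11)
        data = pd.DataFrame(
            [{"group": g, "sex": s}
             for g in ["CU", "prodromalAD", "ADdementia"]
             for s in ["F", "M"] for _ in range(20)])
        data["age"] = rng.normal(70, 8, len(data))
        data["education"] = rng.normal(12, 4, len(data))
        y = rng.normal(size=len(data))
        y[((data.group == "ADdementia") & (data.sex == "F")).to_numpy()] -= 2.0
        res = st.groupwise_sex_family(
            {"out": y}, data, n_perm=400, seed=2)
        assert res[("ADdementia", "out")].p_permutation < 0.05
        assert res[("CU", "out")].p_permutation > 0.05


class TestTrimmedPearson:
    def test_identical_after_trim(self):
        x = np.arange(20.0)
        res = st.trimmed_pearson(x, x, n_perm=200, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(12)
        res = st.trimmed_pearson(
            rng.normal(size=400), rng.normal(size=400), n_perm=200, seed=0)
        assert abs(res.r) < 0.15
        assert res.p_permutation > 0.05

    def test_hand_outlier_excluded(self):
        y = np.array([10, 10, 11, 12, 13, 14, 15, 16, 17, 1000.0])
        x = np.array([1, 2, 2, 3, 4, 4, 5, 6, 7, -50.0])
        res = st.trimmed_pearson(x, y, trim_values=y, n_perm=200, seed=0)
        assert res.n_used == 9 and res.n_excluded == 1
        keep = y <= 17
        assert res.r == pytest.approx(np.corrcoef(x[keep], y[keep])[0, 1])

    def test_degenerate_post_trim(self):
        with pytest.raises(ValueError, match="zero variance"):
            st.trimmed_pearson(np.ones(10), np.arange(10.0), n_perm=10)

    def test_too_few_after_trim(self):
        with pytest.raises(ValueError, match="fewer than 4"):
            st.trimmed_pearson(np.arange(3.0), np.arange(3.0), n_perm=10)
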