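"""The statistical battery against closed forms, enumeration oracles,
and independent implementations (scipy exact modes, pingouin, sklearn).
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from usvscore.stats import (
    bonferroni,
    cohen_kappa,
    fit_mixed_model,
    posthoc_pairwise,
    rank_test,
    rm_anova_within,
    t_test,
)


class TestTTest:
    def test_one_sample_centered(self):
        r = t_test("one_sample", [49, 50, 51], 50.0)
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_one_sample_closed_form(self):
        # mean 54, sd 2 -> t = 4 / (2/sqrt(3)) = 3.4641, df 2
        r = t_test("one_sample", [52, 54, 56], 50.0)
        assert r.statistic == pytest.approx(3.4641, abs=1e-4)
        assert r.df == 2
        assert r.effect == pytest.approx(2.0)  # Cohen's d = 4/2

    def test_paired_closed_form(self):
        # differences (2, 1, 2): mean 5/3, sd 1/sqrt(3) -> t = 5, df 2
        r = t_test("paired", [3, 3, 5], [1, 2, 3])
        assert r.statistic == pytest.approx(5.0)
        assert r.df == 2

    def test_independent_matches_scipy(self):
        x, y = [1.0, 2.0, 4.0, 3.0], [2.5, 4.0, 5.0]
        r = t_test("independent", x, y)
        ref = sps.ttest_ind(x, y)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)

    def test_zero_variance_flagged_degenerate(self):
        r = t_test("one_sample", [50, 50, 50], 50.0)
        assert r.degenerate and math.isnan(r.statistic)


class TestRmAnova:
    def test_two_level_factor_equals_paired_t_squared(self):
        df = pd.DataFrame({
            "s": ["s1", "s1", "s2", "s2", "s3", "s3"],
            "cond": ["a", "b"] * 3,
            "y": [10, 13, 20, 22, 30, 35],
        })
        (res,) = rm_anova_within(df, "y", "s", ["cond"])
        assert res.statistic == pytest.approx(14.2857, abs=1e-3)
        assert res.df == (1, 2)
        t = t_test("paired", [13, 22, 35], [10, 20, 30])
        assert res.statistic == pytest.approx(t.statistic ** 2, abs=1e-8)

    def test_constant_dv_gives_zero_f(self):
        df = pd.DataFrame({
            "s": ["s1", "s1", "s2", "s2"],
            "cond": ["a", "b"] * 2,
            "y": [3.0, 3.0, 7.0, 7.0],
        })
        (res,) = rm_anova_within(df, "y", "s", ["cond"])
        assert res.statistic == 0.0

    @staticmethod
    def _brute_force_two_way(y):
        """Independent sums-of-squares decomposition on y[s, a, b]."""
        s, a, b = y.shape
        m = y.mean()
        A = y.mean(axis=(0, 2))
        B = y.mean(axis=(0, 1))
        S = y.mean(axis=(1, 2))
        AB = y.mean(axis=0)
        AS = y.mean(axis=2)
        BS = y.mean(axis=1)
        ss = {}
        ss["A"] = s * b * ((A - m) ** 2).sum()
        ss["B"] = s * a * ((B - m) ** 2).sum()
        ss["AB"] = s * ((AB - A[:, None] - B[None, :] + m) ** 2).sum()
        ss["AS"] = b * ((AS - S[:, None] - A[None, :] + m) ** 2).sum()
        ss["BS"] = a * ((BS - S[:, None] - B[None, :] + m) ** 2).sum()
        ss_abs = 0.0
        for i in range(s):
            for j in range(a):
                for k in range(b):
                    ss_abs += (y[i, j, k] - AB[j, k] - AS[i, j] - BS[i, k]
                               + A[j] + B[k] + S[i] - m) ** 2
        ss["ABS"] = ss_abs
        f = {
            "A": (ss["A"] / (a - 1)) / (ss["AS"] / ((a - 1) * (s - 1))),
            "B": (ss["B"] / (b - 1)) / (ss["BS"] / ((b - 1) * (s - 1))),
            "AB": (ss["AB"] / ((a - 1) * (b - 1)))
                  / (ss["ABS"] / ((a - 1) * (b - 1) * (s - 1))),
        }
        return f

    def test_two_way_matches_brute_force_to_1e10(self):
        rng = np.random.default_rng(123)
        for _ in range(5):
            y = rng.normal(size=(8, 2, 3))
            rows = [
                {"s": f"s{i}", "a": f"a{j}", "b": f"b{k}", "y": y[i, j, k]}
                for i in range(8) for j in range(2) for k in range(3)
            ]
            res = rm_anova_within(pd.DataFrame(rows), "y", "s", ["a", "b"])
            oracle = self._brute_force_two_way(y)
            assert res[0].statistic == pytest.approx(oracle["A"], abs=1e-10)
            assert res[1].statistic == pytest.approx(oracle["B"], abs=1e-10)
            assert res[2].statistic == pytest.approx(oracle["AB"], abs=1e-10)

    def test_two_way_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        rows = [
            {"s": f"s{i}", "a": f"a{j}", "b": f"b{k}", "y": rng.normal()}
            for i in range(8) for j in range(2) for k in range(3)
        ]
        df = pd.DataFrame(rows)
        mine = rm_anova_within(df, "y", "s", ["a", "b"])
        ref = pg.rm_anova(data=df, dv="y", within=["a", "b"], subject="s",
                          detailed=True)
        for r, (_, row) in zip(mine, ref.iterrows()):
            assert r.statistic == pytest.approx(row["F"], abs=1e-8)
            assert r.p == pytest.approx(row["p_unc"], abs=1e-8)

    def test_missing_cell_rejected(self):
        df = pd.DataFrame({
            "s": ["s1", "s1", "s2"],
            "cond": ["a", "b", "a"],
            "y": [1.0, 2.0, 3.0],
        })
        with pytest.raises(ValueError, match="balanced"):
            rm_anova_within(df, "y", "s", ["cond"])


class TestPosthoc:
    def test_bonferroni_examples(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)
        assert bonferroni(0.02, 3) == pytest.approx(0.06)
        assert bonferroni(0.03, 3) == pytest.approx(0.09)
        assert bonferroni(0.4, 1) == pytest.approx(0.4)
        assert bonferroni(0.6, 3) == 1.0  # capped

    def test_pairwise_count_and_adjustment(self):
        rng = np.random.default_rng(5)
        rows = [{"s": f"s{i}", "cond": c, "y": rng.normal()}
                for i in range(6) for c in ("a", "b", "c")]
        res = posthoc_pairwise(pd.DataFrame(rows), "y", "s", "cond")
        assert len(res) == 3
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p * 3))


class TestRankTests:
    def test_kruskal_wallis_closed_form(self):
        r = rank_test("kruskal_wallis", [1, 2, 3], [4, 5, 6],
                      method="asymptotic")
        assert r.statistic == pytest.approx(3.8571, abs=1e-4)

    def test_mann_whitney_u_is_zero_for_separated_groups(self):
        r = rank_test("mann_whitney", [1, 2, 3], [4, 5, 6], method="exact")
        assert r.statistic == 0.0

    def test_friedman_identical_ordering(self):
        data = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]], dtype=float)
        r = rank_test("friedman", data, method="asymptotic")
        assert r.statistic == pytest.approx(6.0)

    def test_wilcoxon_all_positive_diffs(self):
        r = rank_test("wilcoxon_signed_rank", [1, 2, 3], method="exact")
        assert r.statistic == 0.0  # W- carries no rank mass

    def test_wilcoxon_all_zero_diffs_degenerate(self):
        r = rank_test("wilcoxon_signed_rank", [0.0, 0.0], method="exact")
        assert r.degenerate

    def test_mann_whitney_u_complementarity(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=5), rng.normal(size=7)
        u_xy = rank_test("mann_whitney", x, y, method="asymptotic").statistic
        u_yx = rank_test("mann_whitney", y, x, method="asymptotic").statistic
        assert u_xy + u_yx == pytest.approx(5 * 7)

    def test_two_group_kruskal_equals_mann_whitney_p(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=12), rng.normal(0.5, 1, size=15)
        p_kw = rank_test("kruskal_wallis", x, y, method="asymptotic").p
        p_mw = rank_test("mann_whitney", x, y, method="asymptotic").p
        assert p_kw == pytest.approx(p_mw, abs=1e-6)

    # ---- exact nulls vs full enumeration ----

    def test_exact_mann_whitney_matches_scipy(self):
        x, y = [1.2, 3.4, 0.5], [2.2, 5.1, 4.4, 6.0]
        mine = rank_test("mann_whitney", x, y, method="exact")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert mine.p == pytest.approx(ref.pvalue)

    def test_exact_wilcoxon_matches_scipy(self):
        d = [1.5, -0.5, 2.5, 3.0, -4.0, 0.7]
        mine = rank_test("wilcoxon_signed_rank", d, method="exact")
        ref = sps.wilcoxon(d, method="exact")
        assert mine.p == pytest.approx(ref.pvalue)

    def test_exact_kruskal_matches_enumeration(self):
        groups = [[1.0, 5.0, 3.0], [2.0, 8.0], [7.0, 4.0]]
        mine = rank_test("kruskal_wallis", *groups, method="exact")
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        h_obs = sps.kruskal(*groups).statistic
        count = total = 0
        for perm in itertools.permutations(pooled):
            gs, at = [], 0
            for n in sizes:
                gs.append(list(perm[at:at + n]))
                at += n
            count += sps.kruskal(*gs).statistic >= h_obs - 1e-12
            total += 1
        assert mine.p == pytest.approx(count / total)

    def test_exact_friedman_matches_enumeration(self):
        data = np.array([[0.1, 0.9, 0.4],
                         [1.2, 0.3, 0.8],
                         [0.2, 0.7, 0.5],
                         [0.9, 0.1, 0.6]])
        mine = rank_test("friedman", data, method="exact")
        chi_obs = sps.friedmanchisquare(*data.T).statistic
        count = total = 0
        for perms in itertools.product(
                *[itertools.permutations(row) for row in data]):
            mat = np.array(perms)
            count += sps.friedmanchisquare(*mat.T).statistic >= chi_obs - 1e-12
            total += 1
        assert mine.p == pytest.approx(count / total)

    def test_statistics_match_scipy_on_ties(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0]
        y = [2.0, 4.0, 4.0, 6.0]
        mine = rank_test("kruskal_wallis", x, y, method="asymptotic")
        ref = sps.kruskal(x, y)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p == pytest.approx(ref.pvalue)


class TestMixedModel:
    @staticmethod
    def _balanced(dv_fn, n_animals=8, noise=None, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_animals):
            shift = 0.3 * i
            for c in (2.0, 5.0, 10.0):
                y = dv_fn(c) + shift
                if noise:
                    y += rng.normal(0, noise)
                rows.append({"animal": f"a{i}", "sucrose_percent": c,
                             "dcvs": y})
        return pd.DataFrame(rows)

    def test_noiseless_slope_recovered_exactly(self):
        df = self._balanced(lambda c: 0.1 + 0.034 * c)
        fit = fit_mixed_model(df, "dcvs")
        assert fit.slope == pytest.approx(0.034, abs=1e-8)
        assert fit.ci_low <= fit.slope <= fit.ci_high

    def test_reml_path_on_noisy_data(self):
        df = self._balanced(lambda c: 0.05 + 0.03 * c, noise=0.05, seed=4)
        fit = fit_mixed_model(df, "dcvs")
        assert fit.method == "mixed-reml"
        assert fit.re_variance > 0
        assert 0 <= fit.r2_marginal <= 1
        assert fit.n_obs == 24 and fit.n_groups == 8

    def test_wald_ci_df_matches_design(self):
        # 24 observations, 8 animals, 1 slope -> 15 residual df
        df = self._balanced(lambda c: 0.05 + 0.03 * c, noise=0.05, seed=4)
        fit = fit_mixed_model(df, "dcvs", ci_method="wald")
        assert fit.df == 15

    def test_single_condition_rejected(self):
        df = pd.DataFrame({"animal": ["a", "b"], "sucrose_percent": [5.0, 5.0],
                           "dcvs": [0.1, 0.2]})
        with pytest.raises(ValueError):
            fit_mixed_model(df, "dcvs")


class TestKappa:
    def test_identical_sequences(self):
        assert cohen_kappa(list("AABB"), list("AABB")) == pytest.approx(1.0)

    def test_chance_level(self):
        # p_o = 0.5, p_e = 0.5 -> kappa 0
        assert cohen_kappa(list("AABB"), list("ABAB")) == pytest.approx(0.0)

    def test_agreement_table_closed_form(self):
        # {AA: 45, AB: 5, BA: 5, BB: 45}: p_o 0.9, p_e 0.5 -> kappa 0.8
        a = ["A"] * 50 + ["B"] * 50
        b = ["A"] * 45 + ["B"] * 5 + ["A"] * 5 + ["B"] * 45
        assert cohen_kappa(a, b) == pytest.approx(0.8)

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(11)
        a = rng.choice(list("ABC"), 200)
        b = rng.choice(list("ABC"), 200)
        assert cohen_kappa(a, b) == pytest.approx(
            sk.cohen_kappa_score(a, b))
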