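"""Group statistics: transform, ANOVA, Holm, pairwise and paired contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from connfit import (
    DataError,
    arcsine_sqrt,
    eta_squared_from_f,
    holm_adjust,
    laterality_tests,
    median_by,
    one_way_anova,
    pairwise_t_tests,
)


class TestArcsineSqrt:
    def test_endpoints_and_closed_form(self):
        assert arcsine_sqrt(np.array([0.0]))[0] == 0.0
        assert arcsine_sqrt(np.array([1.0]))[0] == pytest.approx(np.pi / 2)
        assert arcsine_sqrt(np.array([0.25]))[0] == pytest.approx(np.pi / 6)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(x=st.floats(0, 1), y=st.floats(0, 1))
    def test_strictly_increasing(self, x, y):
        if x < y:
            assert arcsine_sqrt(np.array([x]))[0] < arcsine_sqrt(np.array([y]))[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            arcsine_sqrt(np.array([1.01]))


class TestMedianBy:
    def test_order_statistics(self):
        table = pd.DataFrame(
            {
                "category": ["a", "a", "b", "c", "c", "c"],
                "r2": [0.2, 0.8, 0.4, 0.1, 0.9, 0.5],
            }
        )
        got = median_by(table, "category", seed=0).set_index("category")["median"]
        assert got["a"] == pytest.approx(0.5)
        assert got["b"] == pytest.approx(0.4)  # singleton
        assert got["c"] == pytest.approx(0.5)

    def test_bootstrap_se_seeded(self):
        table = pd.DataFrame({"lobe": ["x"] * 30,
                              "r2": np.random.default_rng(0).uniform(size=30)})
        a = median_by(table, "lobe", seed=4)
        b = median_by(table, "lobe", seed=4)
        assert a["se_boot"].iloc[0] == b["se_boot"].iloc[0] > 0

    def test_unknown_grouping_rejected(self):
        with pytest.raises(DataError, match="grouping"):
            median_by(pd.DataFrame({"r2": [0.1]}), "galaxy")


class TestAnova:
    def test_hand_decomposition(self):
        """Groups {1,2,3} and {4,5,6}: SSb=13.5, SSw=4, F=13.5 on (1,4) df."""
        res = one_way_anova(np.array([1, 2, 3, 4, 5, 6], float),
                            ["a"] * 3 + ["b"] * 3)
        assert res.f_stat == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.eta_squared == pytest.approx(13.5 / 17.5)

    def test_matches_scipy_f_oneway(self):
        import scipy.stats

        rng = np.random.default_rng(1)
        groups = [rng.standard_normal(n) + mu for n, mu in [(12, 0), (9, 0.5), (15, -0.2)]]
        labels = np.repeat(["a", "b", "c"], [12, 9, 15])
        res = one_way_anova(np.concatenate(groups), labels)
        ref = scipy.stats.f_oneway(*groups)
        assert res.f_stat == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_identical_means_give_zero_f(self):
        res = one_way_anova(np.array([1.0, 2.0, 1.0, 2.0]), ["a", "a", "b", "b"])
        assert res.f_stat == 0.0 and res.eta_squared == 0.0

    def test_ss_identity_on_random_data(self):
        rng = np.random.default_rng(2)
        values = rng.standard_normal(100)
        labels = rng.choice(list("abcd"), size=100)
        res = one_way_anova(values, labels)
        ss_total = float(np.sum((values - values.mean()) ** 2))
        ss_between = res.eta_squared * ss_total
        ss_within = ss_total - ss_between
        f_rebuilt = (ss_between / res.df_between) / (ss_within / res.df_within)
        assert abs(f_rebuilt - res.f_stat) < 1e-8
        # eta^2 identity with F and dfs
        assert res.eta_squared == pytest.approx(
            eta_squared_from_f(res.f_stat, res.df_between, res.df_within), abs=1e-12
        )

    def test_small_group_rejected(self):
        with pytest.raises(DataError):
            one_way_anova(np.array([1.0, 2.0, 3.0]), ["a", "a", "b"])


class TestHolm:
    def test_single_test_unchanged(self):
        assert holm_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_down(self):
        got = holm_adjust([0.001, 0.02, 0.04])
        assert np.allclose(got, [0.003, 0.04, 0.04])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=15)
        ours = holm_adjust(p)
        ref = multipletests(p, method="holm")[1]
        assert np.allclose(ours, ref)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=12))
    def test_monotone_and_dominated_by_bonferroni(self, p):
        p = np.array(p)
        adj = holm_adjust(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in raw rank
        assert np.all(adj <= np.minimum(1, p * p.size) + 1e-15)
        assert np.all(adj >= p - 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(DataError):
            holm_adjust([0.5, 1.2])


class TestPairwise:
    def test_family_size_all_pairs(self):
        rng = np.random.default_rng(4)
        labels = np.repeat([f"c{i}" for i in range(7)], 10)
        values = rng.standard_normal(70)
        res = pairwise_t_tests(values, labels)
        assert len(res) == 21

    def test_hand_effect_size(self):
        """[1,2,3] vs [2,3,4]: pooled SD 1, d = −1, t = −√(3/2) on 4 df."""
        res = pairwise_t_tests(np.array([1, 2, 3, 2, 3, 4], float),
                               ["a"] * 3 + ["b"] * 3)
        (c,) = res
        assert c.cohen_d == pytest.approx(-1.0)
        assert c.t_stat == pytest.approx(-np.sqrt(1.5), abs=1e-12)
        assert c.df == 4

    def test_identical_groups_null(self):
        res = pairwise_t_tests(np.array([1, 2, 3, 1, 2, 3], float),
                               ["a"] * 3 + ["b"] * 3)
        (c,) = res
        assert c.t_stat == 0.0 and c.cohen_d == 0.0 and c.p_raw == pytest.approx(1.0)

    def test_welch_flag_changes_df(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.standard_normal(20), 3 * rng.standard_normal(8)])
        labels = ["a"] * 20 + ["b"] * 8
        student = pairwise_t_tests(values, labels, welch=False)[0]
        welch = pairwise_t_tests(values, labels, welch=True)[0]
        assert student.df == 26
        assert welch.df != 26 and welch.df < 26

    def test_holm_never_reorders_significance(self):
        rng = np.random.default_rng(6)
        values = rng.standard_normal(50) + np.repeat([0, 0.5, 1.2, 0.1, 2.0], 10)
        labels = np.repeat(list("abcde"), 10)
        res = pairwise_t_tests(values, labels)
        raw = np.array([c.p_raw for c in res])
        adj = np.array([c.p_holm for c in res])
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj >= raw - 1e-15)


class TestLaterality:
    def _table(self, parc, lh_vals, rh_vals, domain=0):
        pairs = parc.homolog_pairs()
        rows = []
        for (l, r), lv, rv in zip(pairs, lh_vals, rh_vals):
            rows.append({"region_id": l, "domain_id": domain, "r2_transformed": lv})
            rows.append({"region_id": r, "domain_id": domain, "r2_transformed": rv})
        return pd.DataFrame(rows)

    def test_exact_symmetry_gives_null(self, small_parcellation):
        vals = np.linspace(0.3, 0.9, 4)
        table = self._table(small_parcellation, vals, vals)
        (res,) = laterality_tests(table, [0], small_parcellation)
        assert res.t_stat == 0.0 and res.p_raw == 1.0 and res.cohen_d == 0.0

    def test_constant_nonzero_shift_is_error(self, small_parcellation):
        # exactly representable values so the pairwise difference is constant
        vals = np.array([0.0, 0.25, 0.5, 0.75])
        table = self._table(small_parcellation, vals + 0.5, vals)
        with pytest.raises(DataError, match="zero-variance"):
            laterality_tests(table, [0], small_parcellation)

    def test_df_equals_pairs_minus_one(self, small_parcellation):
        rng = np.random.default_rng(7)
        table = self._table(small_parcellation, rng.uniform(size=4), rng.uniform(size=4))
        (res,) = laterality_tests(table, [0], small_parcellation)
        assert res.df == 3
        assert res.test_kind == "paired"

    def test_matches_scipy_paired(self, small_parcellation):
        import scipy.stats

        rng = np.random.default_rng(8)
        lh, rh = rng.uniform(size=4), rng.uniform(size=4)
        table = self._table(small_parcellation, lh, rh)
        (res,) = laterality_tests(table, [0], small_parcellation)
        ref = scipy.stats.ttest_rel(lh, rh)
        assert res.t_stat == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-10)

    def test_planted_shift_detected_with_high_power(self):
        """41 pairs, mean gap 0.1, sd 0.1: noncentral-t power > 0.99 at α=0.05."""
        import scipy.stats

        n = 41
        ncp = 0.1 / (0.1 / np.sqrt(n))  # = sqrt(41) ≈ 6.4
        crit = scipy.stats.t.ppf(0.975, n - 1)
        power = scipy.stats.nct.sf(crit, n - 1, ncp)
        assert power > 0.99
        # simulated rejection with one draw
        rng = np.random.default_rng(9)
        diffs = 0.1 + 0.1 * rng.standard_normal(n)
        t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(n))
        assert abs(t) > crit

    def test_missing_fit_for_domain_rejected(self, small_parcellation):
        table = self._table(small_parcellation, np.arange(4.0), np.arange(4.0))
        with pytest.raises(DataError, match="domain 3"):
            laterality_tests(table, [3], small_parcellation)
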