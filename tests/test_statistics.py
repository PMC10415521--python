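"""Statistical layer: CV, Bland–Altman, rank tests, Spearman, regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn
from scipy import stats as sps

from mrbpe.statistics import (bland_altman, coefficient_of_variation,
                              cohort_compare, holm_bonferroni,
                              kurtosis_regression, mann_whitney_u, paired_t,
                              spearman_r, student_t, wilcoxon_signed_rank)


class TestCoefficientOfVariation:
    def test_zero_dispersion(self):
        assert coefficient_of_variation([[10, 10]]).cv_pct == 0.0

    def test_hand_computed_example(self):
        # sample SD of {8, 12} is 2*sqrt(2), mean 10
        res = coefficient_of_variation([[8, 12]])
        assert res.cv_pct == pytest.approx(100 * 2 * np.sqrt(2) / 10, rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(k=stn.floats(0.01, 100))
    def test_scale_invariance(self, k):
        base = [[8.0, 12.0, 9.0], [20.0, 22.0]]
        scaled = [[k * v for v in reps] for reps in base]
        assert coefficient_of_variation(scaled).cv_pct == pytest.approx(
            coefficient_of_variation(base).cv_pct, rel=1e-9)

    def test_pooling_is_rms_of_per_subject_cvs(self):
        res = coefficient_of_variation([[8, 12], [10, 10], [5, 15]])
        expected = np.sqrt(np.mean(np.square(res.per_subject_cv_pct)))
        assert res.cv_pct == pytest.approx(expected, rel=1e-12)

    def test_zero_mean_subject_excluded_with_warning(self):
        with pytest.warns(RuntimeWarning, match="zero mean"):
            res = coefficient_of_variation([[-1.0, 1.0], [9.0, 11.0]])
        assert res.n_subjects == 1

    def test_single_repeat_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([[5.0]])


class TestBlandAltman:
    def test_hand_computed_example(self):
        res = bland_altman([(1, 2), (2, 2), (3, 2)])
        assert res.bias == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.rpc == pytest.approx(1.96)
        assert res.loa_low == pytest.approx(-1.96)
        assert res.loa_high == pytest.approx(1.96)

    def test_identical_pairs(self):
        res = bland_altman([(5, 5), (7, 7), (9, 9)])
        assert res.bias == 0.0 and res.rpc == 0.0

    def test_swapping_sides_negates_bias_preserves_rpc(self, rng):
        pairs = rng.normal(10, 2, size=(15, 2))
        a = bland_altman(pairs)
        b = bland_altman(pairs[:, ::-1])
        assert b.bias == pytest.approx(-a.bias)
        assert b.rpc == pytest.approx(a.rpc)

    def test_order_invariance(self, rng):
        pairs = rng.normal(10, 2, size=(12, 2))
        a = bland_altman(pairs)
        b = bland_altman(pairs[::-1])
        assert (a.bias, a.rpc) == pytest.approx((b.bias, b.rpc))

    def test_points_export_matches_axes(self):
        res = bland_altman([(3, 1), (5, 3)])
        np.testing.assert_allclose(res.points,
                                   [[2.0, 2.0], [4.0, 2.0]])

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([(1, 2)])


def mw_enumeration_oracle(a, b):
    """Independent exact Mann–Whitney p: enumerate all labelings."""
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)

    def u_of(idx):
        ranks = sps.rankdata(pooled)
        return ranks[list(idx)].sum() - na * (na + 1) / 2

    mean_u = na * (n - na) / 2
    dev = abs(u_of(range(na)) - mean_u)
    hits = total = 0
    for combo in itertools.combinations(range(n), na):
        total += 1
        if abs(u_of(combo) - mean_u) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestRankTests:
    def test_identical_samples_give_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0 and res.exact_flag

    def test_fully_separated_small_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)   # 2 of C(6,3)=20 labelings
        assert res.exact_flag

    def test_exact_p_equals_enumeration_oracle(self, rng):
        for _ in range(12):
            na, nb = rng.integers(3, 7, size=2)
            a, b = rng.normal(size=na), rng.normal(0.5, 1, size=nb)
            if rng.random() < 0.4:
                b[0] = a[0]  # inject a tie
            res = mann_whitney_u(a, b)
            assert res.exact_flag
            assert res.p_value == pytest.approx(mw_enumeration_oracle(a, b),
                                                abs=1e-12)

    def test_exact_matches_scipy_on_tie_free_data(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=6)
        res = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        """n=10 vs 10 sits above the enumeration limit; its asymptotic p
        should sit within 0.02 of a direct exact computation."""
        a, b = rng.normal(size=10), rng.normal(0.3, 1, size=10)
        res = mann_whitney_u(a, b)
        assert not res.exact_flag
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=0.02)

    def test_wilcoxon_exact_equals_sign_enumeration(self, rng):
        for _ in range(8):
            n = int(rng.integers(5, 11))
            a = rng.normal(size=n)
            b = a + rng.normal(0.3, 0.5, size=n)
            res = wilcoxon_signed_rank(a, b)
            assert res.exact_flag
            d = a - b
            d = d[d != 0]
            ranks = sps.rankdata(np.abs(d))
            mean_w = d.size * (d.size + 1) / 4
            dev = abs(ranks[d > 0].sum() - mean_w)
            hits = sum(
                1 for signs in itertools.product((0, 1), repeat=d.size)
                if abs(sum(r for s, r in zip(signs, ranks) if s) - mean_w)
                >= dev - 1e-12)
            assert res.p_value == pytest.approx(hits / 2 ** d.size, abs=1e-12)

    def test_wilcoxon_all_zero_differences_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_t_tests_match_scipy(self, rng):
        a, b = rng.normal(size=9), rng.normal(0.4, 1, size=11)
        res = student_t(a, b)
        ref = sps.ttest_ind(a, b)
        assert (res.statistic, res.p_value) == pytest.approx(
            (ref.statistic, ref.pvalue))
        c = rng.normal(size=9)
        res_p = paired_t(a, c)
        ref_p = sps.ttest_rel(a, c)
        assert (res_p.statistic, res_p.p_value) == pytest.approx(
            (ref_p.statistic, ref_p.pvalue))


class TestSpearman:
    def test_monotone_relationships(self):
        x = np.arange(10.0)
        assert spearman_r(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman_r(x, -x**3)[0] == pytest.approx(-1.0)

    def test_matches_two_step_rank_then_pearson_oracle(self, rng):
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        r, _ = spearman_r(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_permutation_p_reasonable_under_null(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        _, p = spearman_r(x, y, permutation=True, n_perm=2000, rng_seed=4)
        assert 0.0 < p <= 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="rank variance"):
            spearman_r([1, 1, 1, 1], [1, 2, 3, 4])


class TestKurtosisRegression:
    def test_noiseless_coefficients_recovered(self, rng):
        age = rng.uniform(40, 50, 40)
        risk = (np.arange(40) < 20).astype(float)
        y = 2.0 + 0.3 * age - 1.5 * risk + 0.1 * age * risk
        res = kurtosis_regression(y, age, risk)
        assert res.coefficients["intercept"] == pytest.approx(2.0, abs=1e-8)
        assert res.coefficients["age"] == pytest.approx(0.3, abs=1e-8)
        assert res.coefficients["risk"] == pytest.approx(-1.5, abs=1e-8)
        assert res.coefficients["age:risk"] == pytest.approx(0.1, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        age = rng.uniform(40, 50, 35)
        risk = rng.integers(0, 2, 35).astype(float)
        y = 5 - 0.2 * age + 3 * risk + rng.normal(size=35)
        res = kurtosis_regression(y, age, risk)
        x = np.column_stack([np.ones(35), age, risk, age * risk])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        got = [res.coefficients[k] for k in ("intercept", "age", "risk",
                                             "age:risk")]
        assert got == pytest.approx(beta, abs=1e-8)

    def test_cis_contain_their_coefficients(self, rng):
        age = rng.uniform(40, 50, 30)
        risk = rng.integers(0, 2, 30).astype(float)
        y = rng.normal(size=30)
        res = kurtosis_regression(y, age, risk)
        for name, coef in res.coefficients.items():
            lo, hi = res.conf_int[name]
            assert lo <= coef <= hi

    def test_single_group_with_risk_term_is_collinear(self, rng):
        age = rng.uniform(40, 50, 20)
        risk = np.zeros(20)
        with pytest.raises(ValueError, match="rank deficient"):
            kurtosis_regression(rng.normal(size=20), age, risk)


class TestCohortCompare:
    @staticmethod
    def _table(rng, shift=0.0):
        rows = []
        for grp, n in (("high_risk", 12), ("population_risk", 12)):
            for i in range(n):
                rows.append({
                    "subject": f"{grp}{i}", "group": grp,
                    "mrbd_pct": rng.normal(12, 3),
                    "bpe_kurtosis": rng.normal(
                        5 + (shift if grp == "high_risk" else 0), 1),
                })
        return pd.DataFrame(rows)

    def test_identical_groups_give_p_one_exact(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        rows = ([{"group": "high_risk", "m": v} for v in vals]
                + [{"group": "population_risk", "m": v} for v in vals])
        out = cohort_compare(pd.DataFrame(rows), ["m"],
                             test_overrides={"m": "mw"})
        assert out.loc[0, "p_value"] == 1.0
        assert out.loc[0, "exact"]

    def test_row_bookkeeping_and_skip(self, rng, caplog):
        table = self._table(rng)
        table.loc[table["group"] == "high_risk", "bpe_kurtosis"] = np.nan
        out = cohort_compare(table, ["mrbd_pct", "bpe_kurtosis"])
        assert list(out["metric"]) == ["mrbd_pct"]

    def test_table_shape_mirrors_group_summary_layout(self, rng):
        out = cohort_compare(self._table(rng), ["mrbd_pct", "bpe_kurtosis"])
        for col in ("high_risk_median", "high_risk_q1", "high_risk_q3",
                    "population_risk_median", "test", "p_value"):
            assert col in out.columns
        assert len(out) == 2

    def test_injected_shift_detected(self, rng):
        out = cohort_compare(self._table(rng, shift=3.0), ["bpe_kurtosis"],
                             test_overrides={"bpe_kurtosis": "mw"})
        assert out.loc[0, "p_value"] < 0.05


def test_holm_bonferroni_monotone_and_bounded():
    p = [0.01, 0.04, 0.03, 0.5]
    adj = holm_bonferroni(p)
    assert np.all(adj >= p)
    assert np.all(adj <= 1.0)
    assert adj[0] == pytest.approx(0.04)
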