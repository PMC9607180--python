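"""Contingency tables, Fisher exact test, Friedman test, report assembly."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facedev.cohort_stats import (
    FriedmanResult,
    contingency_table,
    fisher_exact_two_sided,
    friedman_test,
    holm_adjust,
    report_tables,
)


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive enumeration with exact rational arithmetic."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)

    def prob(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        if prob(k) <= p_obs:
            total += prob(k)
    return float(total)


class TestContingencyTable:
    def _flags(self, men_flagged, n_men, women_flagged, n_women, region="r"):
        flags = [True] * men_flagged + [False] * (n_men - men_flagged)
        flags += [True] * women_flagged + [False] * (n_women - women_flagged)
        sex = ["M"] * n_men + ["F"] * n_women
        idx = [f"s{i}" for i in range(len(sex))]
        return (
            pd.DataFrame({region: flags}, index=idx),
            pd.Series(sex, index=idx),
        )

    def test_orbital_style_counts(self):
        # 17/19 men and 24/41 women -> total 41/60 = 68.3%
        flags, sex = self._flags(17, 19, 24, 41)
        t = contingency_table(flags, sex)["r"]
        assert (t.a, t.b, t.c, t.d) == (17, 2, 24, 17)
        assert round(t.pct_total, 1) == 68.3
        assert round(t.pct_men, 1) == 89.5
        assert round(t.pct_women, 1) == 58.5

    def test_apex_style_counts(self):
        # 3/19 men and 1/41 women -> total 4/60 = 6.7%
        flags, sex = self._flags(3, 19, 1, 41)
        t = contingency_table(flags, sex)["r"]
        assert round(t.pct_total, 1) == 6.7
        assert round(t.pct_men, 1) == 15.8
        assert round(t.pct_women, 1) == 2.4

    def test_zero_flags(self):
        flags, sex = self._flags(0, 19, 0, 41)
        t = contingency_table(flags, sex)["r"]
        assert t.pct_men == t.pct_women == t.pct_total == 0.0

    def test_nan_flags_excluded_pairwise(self):
        flags = pd.DataFrame({"r": [True, np.nan, False]}, index=["a", "b", "c"])
        sex = pd.Series(["M", "M", "F"], index=["a", "b", "c"])
        t = contingency_table(flags, sex)["r"]
        assert t.n == 2

    def test_unknown_sex_errors(self):
        flags = pd.DataFrame({"r": [True]}, index=["a"])
        sex = pd.Series(["X"], index=["a"])
        with pytest.raises(ValueError, match="unknown sex"):
            contingency_table(flags, sex)


class TestFisherExact:
    def test_no_events_p_is_one(self):
        assert fisher_exact_two_sided(0, 19, 0, 41) == 1.0

    def test_matches_enumeration_oracle_on_reference_table(self):
        assert fisher_exact_two_sided(9, 10, 7, 34) == pytest.approx(
            fisher_oracle(9, 10, 7, 34), rel=1e-9
        )

    def test_transpose_symmetry(self):
        # swapping rows and columns simultaneously leaves p unchanged
        assert fisher_exact_two_sided(9, 7, 10, 34) == pytest.approx(
            fisher_exact_two_sided(9, 10, 7, 34), rel=1e-12
        )

    def test_row_swap_symmetry(self):
        assert fisher_exact_two_sided(7, 34, 9, 10) == pytest.approx(
            fisher_exact_two_sided(9, 10, 7, 34), rel=1e-12
        )

    def test_matches_scipy(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if a + b + c + d == 0:
                continue
            expected = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                expected, rel=1e-7, abs=1e-12
            )

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(0, 25)] * 4).filter(lambda t: sum(t) > 0))
    def test_property_matches_oracle(self, table):
        a, b, c, d = table
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-9, abs=1e-12
        )

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(0, 0, 0, 0)

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)

    def test_empirical_size_under_null(self):
        # exact test is conservative: rejection rate <= alpha under H0
        rng = np.random.default_rng(7)
        n_men, n_women, p0 = 19, 41, 0.3
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = int(rng.binomial(n_men, p0))
            c = int(rng.binomial(n_women, p0))
            p = fisher_exact_two_sided(a, n_men - a, c, n_women - c)
            rejections += p < 0.05
        assert rejections / reps <= 0.05


class TestFriedman:
    def test_identical_columns_statistic_zero(self):
        m = pd.DataFrame(np.ones((10, 7)))
        res = friedman_test(m)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0
        assert (res.mean_ranks == 4.0).all()  # (k+1)/2 for k=7

    def test_mean_ranks_sum_invariant(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(12, 7)))
        res = friedman_test(m)
        assert res.mean_ranks.sum() == pytest.approx(28.0)  # k(k+1)/2

    def test_toy_matrix_hand_oracle(self):
        # 4 subjects x 3 locations, no ties; ranks computed by hand
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 1.0, 3.0], [1.0, 2.0, 3.0], [1.0, 3.0, 2.0]]
        )
        # rank sums: col0: 1+2+1+1=5, col1: 2+1+2+3=8, col2: 3+3+3+2=11
        # chi2 = 12/(n k (k+1)) * sum Rj^2 - 3 n (k+1) = 12/48*210 - 48 = 4.5
        res = friedman_test(m)
        assert res.statistic == pytest.approx(4.5)
        assert res.df == 2
        np.testing.assert_allclose(res.mean_ranks, [5 / 4, 8 / 4, 11 / 4])

    def test_matches_scipy_with_ties(self):
        from scipy.stats import friedmanchisquare

        rng = np.random.default_rng(2)
        m = np.round(rng.normal(size=(15, 5)), 1)  # rounding induces ties
        res = friedman_test(pd.DataFrame(m))
        stat, p = friedmanchisquare(*(m[:, j] for j in range(5)))
        assert res.statistic == pytest.approx(stat, rel=1e-9)
        assert res.pvalue == pytest.approx(p, rel=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(10, 4))
        r1 = friedman_test(pd.DataFrame(m))
        r2 = friedman_test(pd.DataFrame(np.exp(m)))  # strictly monotone
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_listwise_drop_of_incomplete_rows(self):
        m = pd.DataFrame(np.random.default_rng(4).normal(size=(8, 3)))
        m.iloc[2, 1] = np.nan
        res = friedman_test(m)
        assert res.n_subjects == 7
        assert res.n_dropped == 1

    def test_too_few_columns_errors(self):
        with pytest.raises(ValueError):
            friedman_test(pd.DataFrame(np.ones((5, 2))))

    def test_too_few_subjects_errors(self):
        with pytest.raises(ValueError):
            friedman_test(pd.DataFrame(np.ones((1, 4))))


class TestReportTables:
    def _cohort(self, rng, p_men, p_women, n_men=19, n_women=41, regions=3):
        idx = [f"s{i}" for i in range(n_men + n_women)]
        sex = pd.Series(["M"] * n_men + ["F"] * n_women, index=idx)
        flags = pd.DataFrame(
            {
                f"r{j}": np.concatenate(
                    [rng.random(n_men) < p_men, rng.random(n_women) < p_women]
                )
                for j in range(regions)
            },
            index=idx,
        )
        return flags, sex

    def test_single_region_cohort(self):
        flags = pd.DataFrame({"only": [True, False]}, index=["a", "b"])
        sex = pd.Series(["M", "F"], index=["a", "b"])
        t2, t3, fr = report_tables(flags, sex)
        assert len(t2) == 1
        assert t3 is None and fr is None

    def test_rank_table_sorted_ascending(self):
        rng = np.random.default_rng(5)
        flags, sex = self._cohort(rng, 0.3, 0.3)
        vals = pd.DataFrame(
            rng.normal(size=(60, 7)), columns=[f"loc{j}" for j in range(7)]
        )
        _, t3, fr = report_tables(flags, sex, friedman_values=vals)
        assert (t3["mean_rank"].diff().dropna() >= 0).all()
        assert fr.df == 6

    def test_null_cohort_type_one_rate(self):
        # no sex effect: per-region rejection rate stays below ~alpha
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 200
        for _ in range(reps):
            flags, sex = self._cohort(rng, 0.3, 0.3, regions=1)
            t2, _, _ = report_tables(flags, sex)
            rejections += int(t2["significant"].iloc[0])
        assert rejections / reps <= 0.08

    def test_holm_option(self):
        p = np.array([0.01, 0.04, 0.03, 0.5])
        adj = holm_adjust(p)
        assert (adj >= p).all()
        assert adj.max() <= 1.0
        # step-down: smallest p multiplied by m
        assert adj[0] == pytest.approx(0.04)

    def test_determinism(self):
        rng1 = np.random.default_rng(8)
        rng2 = np.random.default_rng(8)
        f1, s1 = self._cohort(rng1, 0.4, 0.2)
        f2, s2 = self._cohort(rng2, 0.4, 0.2)
        t1, _, _ = report_tables(f1, s1)
        t2, _, _ = report_tables(f2, s2)
        pd.testing.assert_frame_equal(t1, t2)
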