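"""Cohort statistics: normality gate, two-group tests, comparison tables."""

import itertools

import numpy as np
import pandas as pd
import pytest

import plaquestress as ps
from plaquestress.stats import VariableSpec, compare_categorical, median_iqr


class TestNormalityGate:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ps.normality_gate([1.0, 2.0])

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ps.normality_gate([3.0] * 10)

    def test_uniform_detected_nonnormal(self, rng):
        x = rng.uniform(size=5000)
        _, p, is_normal = ps.normality_gate(x)
        assert not is_normal and p < 1e-6

    def test_gaussian_type_i_error_rate(self):
        """Rejection rate of true normals stays within 3 SE of 5% (n=20)."""
        rejections = 0
        reps = 1000
        for seed in range(reps):
            x = np.random.default_rng(seed).normal(size=20)
            _, _, is_normal = ps.normality_gate(x)
            rejections += not is_normal
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se


def exact_mannwhitney_p(a, b):
    """Enumeration oracle: two-sided p over all group assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(idx_a):
        xa = [pooled[i] for i in idx_a]
        xb = [pooled[i] for i in range(len(pooled)) if i not in idx_a]
        return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in xa for y in xb)

    observed = u_stat(tuple(range(n_a)))
    n_b = len(b)
    centre = n_a * n_b / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_stat(idx) - centre) >= abs(observed - centre) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples(self):
        a = np.arange(10.0)
        u, p = ps.compare_continuous(a, a)
        assert u == 50.0  # n^2 / 2
        assert p > 0.9

    def test_fully_separated_small_groups(self):
        """[1,2,3] vs [10,11,12]: U = 0, exact two-sided p = 2/20 = 0.1."""
        u, p = ps.compare_continuous([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_matches_enumeration_oracle(self, rng):
        """Exact p agrees with explicit enumeration on tie-free samples."""
        for _ in range(20):
            a = rng.normal(size=4)
            b = rng.normal(loc=rng.uniform(-1, 1), size=5)
            _, p = ps.compare_continuous(a, b)
            assert p == pytest.approx(exact_mannwhitney_p(a, b), rel=1e-9)

    def test_symmetric_under_group_swap(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(loc=0.5, size=40)
        _, p1 = ps.compare_continuous(a, b)
        _, p2 = ps.compare_continuous(b, a)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ps.compare_continuous([], [1.0])

    def test_power_against_location_shift(self):
        """1-SD shift at n = 40/49 rejects most of the time."""
        hits = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            _, p = ps.compare_continuous(g.normal(size=40), g.normal(loc=1.0, size=49))
            hits += p < 0.05
        assert hits > 95


class TestCategorical:
    def test_identical_distributions_p1(self):
        p, test = compare_categorical([[4, 4], [4, 4]])
        assert test == "fisher"  # small expected counts -> exact branch
        assert p == pytest.approx(1.0)

    def test_fisher_odds_ratio_example(self):
        """2x2 table (8,30 / 24,27): odds ratio 8*27/(30*24) = 0.30."""
        from scipy.stats import fisher_exact

        table = [[8, 30], [24, 27]]
        orat, _ = fisher_exact(table)
        assert orat == pytest.approx(0.30, abs=0.005)
        p, _ = compare_categorical(table)
        assert 0 <= p <= 1

    def test_chi2_branch_for_large_tables(self):
        p, test = compare_categorical([[30, 40, 30], [25, 45, 30]])
        assert test == "chi2"

    def test_ordinal_uses_rank_test(self):
        p, test = compare_categorical(None, ordinal_scores=([0, 1, 2, 2], [0, 0, 1, 1]))
        assert test == "mannwhitney"

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            compare_categorical([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            compare_categorical([[4, 0], [6, 0]])


class TestMedianIQR:
    def test_iqr_is_single_width(self):
        med, iqr = median_iqr([1.0, 2.0, 3.0, 4.0, 5.0])
        assert med == 3.0
        assert iqr == 2.0  # Q3 - Q1 with linear interpolation


class TestComparisonTable:
    def _frame(self, rng, n=40, shift=0.0):
        rows = []
        for g, loc in (("vulnerable", 0.0), ("stable", shift)):
            for _ in range(n):
                rows.append(
                    {
                        "group": g,
                        "x": rng.normal(loc=loc),
                        "flag": bool(rng.random() < 0.5),
                        "score": int(rng.integers(0, 3)),
                    }
                )
        return pd.DataFrame(rows)

    def test_one_group_empty_rejected(self, rng):
        df = self._frame(rng)
        df = df[df.group == "stable"]
        with pytest.raises(ValueError):
            ps.build_comparison_table(df, [VariableSpec("x", "continuous")])

    def test_unknown_variable_rejected(self, rng):
        with pytest.raises(KeyError):
            ps.build_comparison_table(self._frame(rng), [VariableSpec("nope", "continuous")])

    def test_identical_data_not_significant(self, rng):
        df = self._frame(rng)
        df["x"] = 1.0
        df["score"] = 1
        t = ps.build_comparison_table(
            df, [VariableSpec("x", "continuous"), VariableSpec("score", "ordinal")]
        )
        assert not t["significant"].any()

    def test_shifted_variable_flagged(self, rng):
        df = self._frame(rng, n=60, shift=1.5)
        t = ps.build_comparison_table(df, [VariableSpec("x", "continuous")])
        assert t["significant"].all()
        assert t.loc[0, "median_vulnerable"] < t.loc[0, "median_stable"]

    def test_missing_values_reduce_n(self, rng):
        df = self._frame(rng)
        df.loc[df.index[:7], "x"] = np.nan
        t = ps.build_comparison_table(df, [VariableSpec("x", "continuous")])
        assert t.loc[0, "n_vulnerable"] + t.loc[0, "n_stable"] == len(df) - 7

    def test_ordinal_rows_per_level(self, rng):
        df = self._frame(rng)
        t = ps.build_comparison_table(df, [VariableSpec("score", "ordinal")])
        assert set(t["level"]) == {"0", "1", "2"}
        assert t["p_value"].nunique() == 1  # one test per ordinal variable
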