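"""Group statistics vs brute-force formula oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from morphddm.group_stats import (
    metric_clinical_correlations,
    oneway_anova,
    pairwise_t_bonferroni,
    pearson_bonferroni,
    replicate_age_sensitivity,
)


def _pearson_oracle(x, y):
    """Direct covariance-formula Pearson r."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def _anova_oracle(groups):
    """Hand sums-of-squares decomposition over a dict of lists."""
    all_vals = [v for g in groups.values() for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * ((sum(g) / len(g)) - grand) ** 2 for g in groups.values())
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups.values() for v in g)
    df1 = len(groups) - 1
    df2 = len(all_vals) - len(groups)
    return (ssb / df1) / (ssw / df2), df1, df2


class TestPearson:
    def test_self_correlation_is_one(self):
        x = [1.0, 2.0, 5.0, 3.0, 4.0]
        res = pearson_bonferroni(x, x)
        assert res.r == pytest.approx(1.0)

    def test_matches_bruteforce_formula(self):
        x = [1.0, 2.0, 4.0, 4.5, 7.0]
        y = [2.0, 1.5, 3.0, 5.0, 4.0]
        res = pearson_bonferroni(x, y)
        assert res.r == pytest.approx(_pearson_oracle(x, y), abs=1e-10)
        assert res.df == 3

    def test_family_of_one_leaves_p_unchanged(self):
        res = pearson_bonferroni([1, 2, 3, 5], [2, 2, 4, 5], n_family=1)
        assert res.p_adj == res.p_raw

    def test_pairwise_complete_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, 3.9, np.nan]
        res = pearson_bonferroni(x, y)
        assert res.n == 3

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            pearson_bonferroni([1, 1, 1, 1], [1, 2, 3, 4])

    @given(p=st.floats(1e-6, 1.0), m=st.integers(1, 50))
    @settings(max_examples=50, deadline=None)
    def test_bonferroni_monotone_and_capped(self, p, m):
        res_p = min(1.0, p * m)
        assert res_p >= p and res_p <= 1.0


class TestANOVA:
    def test_matches_bruteforce_decomposition(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.5, 3.5, 4.0], "c": [5.0, 6.0, 4.5, 5.5]}
        values = [v for g in groups.values() for v in g]
        labels = [k for k, g in groups.items() for _ in g]
        f, df1, df2, p = oneway_anova(values, labels)
        f_o, d1_o, d2_o = _anova_oracle(groups)
        assert f == pytest.approx(f_o, abs=1e-10)
        assert (df1, df2) == (d1_o, d2_o)

    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 9)
        values = np.concatenate([a, b])
        labels = ["a"] * 12 + ["b"] * 9
        f, *_ = oneway_anova(values, labels)
        t, _ = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2, abs=1e-10)

    def test_invariance_under_shift_and_scale(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, 20)
        labels = ["a"] * 7 + ["b"] * 6 + ["c"] * 7
        f0, *_ = oneway_anova(values, labels)
        f1, *_ = oneway_anova(values + 100.0, labels)
        f2, *_ = oneway_anova(values * 3.5, labels)
        assert f1 == pytest.approx(f0, rel=1e-10)
        assert f2 == pytest.approx(f0, rel=1e-10)

    def test_all_equal_flagged_degenerate(self):
        f, df1, df2, p = oneway_anova([2.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert np.isnan(f) and np.isnan(p)

    def test_singleton_group_named_in_error(self):
        with pytest.raises(ValueError, match="b"):
            oneway_anova([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestPairwiseT:
    def test_identical_groups_give_zero_t(self):
        vals = [1.0, 2.0, 3.0] * 2
        labels = ["a"] * 3 + ["b"] * 3
        table = pairwise_t_bonferroni(vals, labels)
        assert table.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)

    def test_four_groups_give_six_corrected_comparisons(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, 20)
        labels = [g for g in "abcd" for _ in range(5)]
        table = pairwise_t_bonferroni(vals, labels)
        assert len(table) == 6
        assert (table["n_comparisons"] == 6).all()
        assert np.allclose(table["p_adj"], np.minimum(1.0, 6 * table["p_raw"]))

    def test_matches_bruteforce_pooled_t(self):
        a, b, c = [1.0, 2.0, 2.5], [3.0, 3.2, 4.1, 3.8], [0.5, 1.1, 0.8]
        vals = a + b + c
        labels = ["a"] * 3 + ["b"] * 4 + ["c"] * 3
        table = pairwise_t_bonferroni(vals, labels).set_index(["group_a", "group_b"])
        # pooled within-group variance over ALL groups (ANOVA MSW), df = N - k
        msw = (
            sum((v - np.mean(a)) ** 2 for v in a)
            + sum((v - np.mean(b)) ** 2 for v in b)
            + sum((v - np.mean(c)) ** 2 for v in c)
        ) / (10 - 3)
        t_ab = (np.mean(a) - np.mean(b)) / math.sqrt(msw * (1 / 3 + 1 / 4))
        assert table.loc[("a", "b"), "t"] == pytest.approx(t_ab, abs=1e-10)
        assert table.loc[("a", "b"), "df"] == 7


class TestCorrelationTable:
    def _cohort(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "sensitivity": rng.normal(0.25, 0.05, n),
            "perceptual_bias": rng.normal(8, 1, n),
            "scared_child": rng.integers(0, 82, n).astype(float),
            "scared_parent": rng.integers(0, 82, n).astype(float),
            "ari_child": rng.integers(0, 12, n).astype(float),
            "ari_parent": rng.integers(0, 12, n).astype(float),
        })

    def test_family_size_is_all_cells(self):
        table = metric_clinical_correlations(self._cohort())
        assert len(table) == 8
        assert (table["n_family"] == 8).all()
        assert np.allclose(table["p_adj"], np.minimum(1.0, 8 * table["p_raw"]))
        assert (table["df"] == table["n"] - 2).all()


class TestAgeSensitivityReplication:
    def _cohort(self):
        rng = np.random.default_rng(7)
        n = 40
        age = rng.uniform(8, 22, n)
        return pd.DataFrame({
            "age": age,
            "sensitivity": 0.01 * age,  # exact linear function
            "diagnosis": ["Healthy" if i < 10 else "DMDD" for i in range(n)],
        })

    def test_exact_linear_gives_r_one(self):
        res = replicate_age_sensitivity(self._cohort())
        assert res.r == pytest.approx(1.0)

    def test_healthy_rows_excluded_from_n(self):
        res = replicate_age_sensitivity(self._cohort())
        assert res.n == 30
        assert res.df == 28

    def test_matches_bruteforce_r_on_toy_table(self):
        df = pd.DataFrame({
            "age": [9.0, 11.0, 13.0, 15.0, 17.0, 19.0],
            "sensitivity": [0.15, 0.22, 0.19, 0.30, 0.26, 0.33],
            "diagnosis": ["DMDD"] * 6,
        })
        res = replicate_age_sensitivity(df)
        assert res.r == pytest.approx(
            _pearson_oracle(df["age"], df["sensitivity"]), abs=1e-10
        )

    def test_too_few_patients_rejected(self):
        df = pd.DataFrame({
            "age": [9.0, 11.0, 13.0],
            "sensitivity": [0.1, 0.2, 0.3],
            "diagnosis": ["Healthy", "Healthy", "DMDD"],
        })
        with pytest.raises(ValueError):
            replicate_age_sensitivity(df)
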