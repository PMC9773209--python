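"""Outlier fencing, descriptives, omnibus and pairwise tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from speechrestore import (bonferroni_alpha, correlation_screen, describe,
                           fence_adjust, levene, pairwise_welch_bh,
                           welch_anova)


class TestFenceAdjust:
    def test_clean_column_is_identity(self, rng):
        df = pd.DataFrame({"a": rng.normal(0, 1, 50)})
        out, rep = fence_adjust(df, 3.0)
        assert rep.n_adjusted == 0
        assert np.array_equal(out["a"], df["a"])

    def test_hand_computed_example(self):
        df = pd.DataFrame({"a": list(range(1, 11)) + [1000.0]})
        out, rep = fence_adjust(df, 3.0)
        q1, q3, iqr = rep.quartiles["a"]
        assert (q1, q3, iqr) == (3.5, 8.5, 5.0)
        assert rep.n_adjusted == 1
        assert out["a"].iloc[-1] == 8.5  # replaced by Q3, not the fence

    def test_value_exactly_on_fence_retained(self):
        base = list(range(1, 11))
        df = pd.DataFrame({"a": base + [23.5]})  # Q3 + 3*IQR of base+...
        out, rep = fence_adjust(df, 3.0)
        q1, q3, iqr = rep.quartiles["a"]
        assert q3 + 3.0 * iqr == pytest.approx(23.5)  # the value sits on the fence
        assert out["a"].iloc[-1] == 23.5  # inclusive boundary: retained
        assert rep.n_adjusted == 0

    def test_low_outlier_goes_to_q1(self):
        df = pd.DataFrame({"a": list(range(1, 11)) + [-1000.0]})
        out, rep = fence_adjust(df, 3.0)
        assert out["a"].iloc[-1] == rep.quartiles["a"][0]

    def test_ordering_of_untouched_values_preserved(self, rng):
        x = rng.normal(0, 1, 80)
        x[0] = 50.0
        df = pd.DataFrame({"a": x})
        out, rep = fence_adjust(df, 3.0)
        untouched = [i for i in range(80) if i not in {r for r, *_ in rep.adjusted_cells}]
        orig = df["a"].iloc[untouched].rank()
        new = out["a"].iloc[untouched].rank()
        assert np.array_equal(orig, new)

    def test_all_missing_column_errors(self):
        with pytest.raises(ValueError):
            fence_adjust(pd.DataFrame({"a": [np.nan] * 5}), 3.0)


class TestDescribe:
    def test_symmetric_data_zero_skew(self):
        mean, sd, lo, hi, skew, kurt = describe([1.0, 2.0, 3.0])
        assert (mean, lo, hi) == (2.0, 1.0, 3.0)
        assert sd == pytest.approx(1.0)
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_undefined(self):
        with pytest.raises(ValueError):
            describe([5.0, 5.0, 5.0])

    def test_gaussian_excess_kurtosis_near_zero(self):
        x = np.random.default_rng(7).standard_normal(100_000)
        *_, kurt = describe(x)
        assert abs(kurt) < 0.05


class TestLevene:
    def test_identical_groups_zero_statistic(self):
        g = [1.0, 2.0, 3.0, 4.0]
        f, p = levene([g, g, g])
        assert f == pytest.approx(0.0)

    def test_two_group_brute_force_oracle(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0, 2, 15)
        f, p = levene([a, b], center="mean")
        # direct one-way ANOVA on |x - group mean|
        za, zb = np.abs(a - a.mean()), np.abs(b - b.mean())
        f2, p2 = sps.f_oneway(za, zb)
        assert f == pytest.approx(f2)
        assert p == pytest.approx(p2)

    def test_type_i_rate_near_alpha(self, rng):
        hits = 0
        reps = 2000
        for _ in range(reps):
            groups = [rng.normal(0, 1, 20) for _ in range(4)]
            _, p = levene(groups)
            hits += p < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.02)


class TestWelchAnova:
    def test_identical_groups_zero_f(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = welch_anova([g, [x + 0.0 for x in g], g])
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_two_groups_equal_welch_t_squared(self, rng):
        a, b = rng.normal(0, 1, 14), rng.normal(0.8, 2.5, 22)
        res = welch_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=False)
        assert res.F == pytest.approx(t.statistic**2)
        assert res.p == pytest.approx(t.pvalue)
        assert res.df2 == pytest.approx(t.df)

    def test_approaches_classic_anova_in_balanced_equal_variance_limit(self, rng):
        # balanced groups standardized to *exactly* equal sample variance:
        # Welch's weighting then coincides with classic ANOVA up to its
        # small-sample correction factor
        groups = []
        for m in (0.0, 0.1, 0.25):
            g = rng.normal(m, 1.0, 100)
            groups.append(m + (g - g.mean()) / g.std(ddof=1))
        res = welch_anova(groups)
        f_classic, _ = sps.f_oneway(*groups)
        assert res.F == pytest.approx(f_classic, rel=0.05)

    def test_matches_published_implementation(self, rng):
        """Independent oracle: pingouin's Welch ANOVA on the same data."""
        pingouin = pytest.importorskip("pingouin")
        groups = [rng.normal(m, s, n) for m, s, n in
                  [(0, 1, 15), (0.5, 2, 25), (1.0, 0.5, 18)]]
        long = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(["a", "b", "c"], [15, 25, 18]),
        })
        ref = pingouin.welch_anova(long, dv="y", between="g")
        res = welch_anova(groups)
        assert res.F == pytest.approx(float(ref["F"].iloc[0]))
        assert res.df2 == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-3)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-3)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])


class TestPairwiseWelchBH:
    def test_single_pair_adjusted_equals_raw(self, rng):
        df = pairwise_welch_bh([rng.normal(0, 1, 10), rng.normal(1, 1, 10)])
        assert df["p_adj"].iloc[0] == pytest.approx(df["p_raw"].iloc[0])

    def test_bh_hand_example(self):
        """Raw (0.01, 0.02, 0.04) with m=3 adjusts to (0.03, 0.03, 0.04)."""
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_adjustment_monotone_and_all_pairs_present(self, rng):
        groups = [rng.normal(m, 1, 12) for m in (0, 0.3, 1.0, 2.0)]
        df = pairwise_welch_bh(groups, list("abcd"))
        assert len(df) == 6  # C(4,2)
        assert (df["p_adj"] >= df["p_raw"] - 1e-15).all()
        order = df.sort_values("p_raw")
        assert order["p_adj"].is_monotonic_increasing


class TestCorrelationScreen:
    def test_perfect_linear_relation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
        r, p = correlation_screen(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)

    def test_symmetry_and_unit_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (30, 4)), columns=list("abcd"))
        r, _ = correlation_screen(df)
        assert np.allclose(r.values, r.values.T)
        assert np.allclose(np.diag(r.values), 1.0)

    def test_matches_closed_form(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        df = pd.DataFrame({"x": x, "y": y})
        r, p = correlation_screen(df)
        expect = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean())**2) * np.sum((y - y.mean())**2))
        assert r.loc["x", "y"] == pytest.approx(expect)
        t = expect * np.sqrt(3 / (1 - expect**2))
        assert p.loc["x", "y"] == pytest.approx(2 * sps.t.sf(abs(t), 3))

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError):
            correlation_screen(df)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 24, 0.05 / 24),   # prints as 0.00208
        (0.05, 6, 0.05 / 6),     # prints as 0.008
        (0.05, 1, 0.05),
    ])
    def test_arithmetic(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)
        assert round(bonferroni_alpha(0.05, 24), 5) == 0.00208

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
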