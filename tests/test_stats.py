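"""Statistical reporting: Shapiro, ANOVA+LSD letters, t-tests, regressions."""

import itertools

import numpy as np
import pytest

from ldscope import stats
from ldscope.stats import (
    anova_lsd,
    asterisk_code,
    compact_letter_display,
    division_rate,
    linear_correlation,
    normality_check,
    pair_test,
)


class TestNormality:
    def test_normal_samples_pass_most_of_the_time(self):
        rng = np.random.default_rng(0)
        hits = sum(normality_check(
            {"g": rng.normal(size=50)}).p.iloc[0] > 0.05
            for _ in range(100))
        assert hits >= 90

    def test_exponential_samples_fail_most_of_the_time(self):
        rng = np.random.default_rng(1)
        hits = sum(normality_check(
            {"g": rng.exponential(size=50)}).p.iloc[0] < 0.05
            for _ in range(100))
        assert hits >= 90

    def test_constant_sample_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            normality_check({"g": np.ones(10)})

    def test_small_groups_skipped(self):
        out = normality_check({"tiny": [1.0, 2.0],
                               "ok": np.random.default_rng(2).normal(size=10)})
        assert list(out.group) == ["ok"]


class TestAnovaLSD:
    def test_identical_groups_all_lettered_a(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=20)
        values = np.concatenate([base, base, base])
        groups = np.repeat(["D0", "D3", "D7"], 20)
        res = anova_lsd(values, groups)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.letters == ["a", "a", "a"]

    def test_clear_separation_letters(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([10 + 0.01 * rng.normal(size=10),
                                 10 + 0.01 * rng.normal(size=10),
                                 0 + 0.01 * rng.normal(size=10)])
        groups = np.repeat(["a1", "a2", "b"], 10)
        res = anova_lsd(values, groups)
        assert res.letters == ["a", "a", "b"]

    def test_two_group_lsd_equals_pooled_t(self):
        """Algebraic oracle: balanced 2-group LSD p == Student t p."""
        from scipy.stats import ttest_ind
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 15), rng.normal(0.8, 1, 15)
        res = anova_lsd(np.concatenate([x, y]),
                        np.repeat(["x", "y"], 15), gate_on_anova=False)
        _, p_t = ttest_ind(x, y, equal_var=True)
        assert res.lsd_p[0, 1] == pytest.approx(p_t, rel=1e-9)

    def test_f_and_p_match_statsmodels(self):
        """Independent oracle: one-way ANOVA table from statsmodels."""
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        rng = np.random.default_rng(6)
        df = pd.DataFrame({
            "v": rng.normal(size=60) + np.repeat([0.0, 0.5, 1.0], 20),
            "g": np.repeat(["a", "b", "c"], 20)})
        res = anova_lsd(df.v.to_numpy(), df.g.to_numpy())
        tab = sm.stats.anova_lm(ols("v ~ C(g)", data=df).fit())
        assert res.f_statistic == pytest.approx(tab.F.iloc[0], rel=1e-9)
        assert res.p_value == pytest.approx(tab["PR(>F)"].iloc[0], rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            anova_lsd(np.repeat([1.0, 2.0], 5), np.repeat(["a", "b"], 5))

    def test_levels_ordered_as_sampled(self):
        values = np.r_[np.zeros(3), np.ones(3) + 0.1, np.full(3, 0.5)]
        values += np.random.default_rng(7).normal(0, 0.01, 9)
        res = anova_lsd(values, np.repeat(["h72", "D0", "D11"], 3))
        assert res.levels == ["h72", "D0", "D11"]


class TestCompactLetters:
    @staticmethod
    def sound(letters, significant):
        k = len(letters)
        for i, j in itertools.combinations(range(k), 2):
            share = bool(set(letters[i]) & set(letters[j]))
            if significant[i][j]:
                assert not share, (letters, i, j)
            else:
                assert share, (letters, i, j)

    def test_soundness_exhaustive_up_to_5_groups(self):
        """Every possible significance pattern yields a letter display
        where two groups share a letter iff their pair is non-significant."""
        rng = np.random.default_rng(8)
        for k in (2, 3, 4, 5):
            means = np.sort(rng.normal(size=k))[::-1]
            for bits in range(2 ** (k * (k - 1) // 2)):
                sig = np.zeros((k, k), bool)
                b = bits
                for i, j in itertools.combinations(range(k), 2):
                    sig[i, j] = sig[j, i] = bool(b & 1)
                    b >>= 1
                letters = compact_letter_display(means, sig)
                self.sound(letters, sig)

    def test_highest_mean_carries_letter_a(self):
        means = np.array([1.0, 5.0, 3.0])
        sig = np.ones((3, 3), bool)
        np.fill_diagonal(sig, False)
        letters = compact_letter_display(means, sig)
        assert letters[1] == "a"


class TestPairTest:
    def test_identical_samples_ns(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pair_test(x, x)
        assert res.code == "ns"
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("p,code", [
        (0.04, "*"), (0.004, "**"), (0.0004, "***"), (0.2, "ns"),
        (0.05, "ns"), (0.01, "*"), (0.001, "**"),   # boundary -> weaker band
    ])
    def test_asterisk_bands(self, p, code):
        assert asterisk_code(p) == code

    def test_asterisk_code_covers_unit_interval(self):
        for p in np.linspace(0, 1, 1001):
            assert asterisk_code(float(p)) in {"ns", "*", "**", "***"}

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pair_test(np.ones(5), np.ones(5))


class TestRegressionAndGrowth:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = linear_correlation(x, 2 * x)
        assert res["slope"] == pytest.approx(2.0)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_uncorrelated_noise_low_r2(self):
        rng = np.random.default_rng(9)
        res = linear_correlation(rng.normal(size=100), rng.normal(size=100))
        assert res["r_squared"] < 0.1

    def test_r2_invariant_to_axis_scaling(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(size=50)
        r1 = linear_correlation(x, y)["r_squared"]
        r2 = linear_correlation(100 * x, 0.01 * y)["r_squared"]
        assert r2 == pytest.approx(r1)

    @pytest.mark.parametrize("n1,n2,dt,rate", [
        (1e5, 2e5, 1.0, 1.0), (1e5, 1e5, 3.0, 0.0), (1e5, 8e5, 3.0, 1.0),
    ])
    def test_division_rate(self, n1, n2, dt, rate):
        assert division_rate(n1, n2, dt) == pytest.approx(rate)

    def test_division_rate_recovers_preculture_value(self):
        from ldscope import synthetic
        g = synthetic.generate_growth_curve(0.73, 1e5, days=7)
        r = division_rate(g.density_per_ml.iloc[0],
                          g.density_per_ml.iloc[-1], 7.0)
        assert r == pytest.approx(0.73, abs=1e-9)

    def test_division_rate_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            division_rate(0.0, 1e5, 1.0)
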