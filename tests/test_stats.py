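import numpy as np
import pytest
from scipy import stats as sps

from egps.stats import (
    GroupedScores,
    one_way_anova,
    partial_corr_given,
    pearson_corr,
    tukey_hsd,
    welch_t_test,
)

TOY = {
    "a": np.array([4.1, 5.2, 6.3, 5.0]),
    "b": np.array([6.9, 7.4, 8.1, 7.7]),
    "c": np.array([5.5, 6.1, 5.9, 6.4]),
}


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_equals_pooled_t_squared(self, rng):
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=6)
        f_res = one_way_anova({"a": a, "b": b})
        t_stat, t_p = sps.ttest_ind(a, b, equal_var=True)
        assert f_res.statistic == pytest.approx(t_stat**2, abs=1e-10)
        assert f_res.p_value == pytest.approx(t_p, abs=1e-12)

    def test_matches_reference_implementation(self):
        res = one_way_anova(TOY)
        ref = sps.f_oneway(*TOY.values())
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-8)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_degenerate_all_equal_reports_p_one(self):
        with pytest.warns(UserWarning):
            res = one_way_anova({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert res.p_value == 1.0

    def test_invariance_to_ordering_and_shift(self):
        base = one_way_anova(TOY)
        reordered = one_way_anova(dict(reversed(list(TOY.items()))))
        shifted = one_way_anova({k: v + 100.0 for k, v in TOY.items()})
        assert reordered.statistic == pytest.approx(base.statistic, abs=1e-10)
        assert shifted.statistic == pytest.approx(base.statistic, abs=1e-8)

    def test_type_one_error_under_global_null(self):
        """ANOVA p-values are uniform under the null: rejection rate at
        alpha=0.05 lies in 0.05 +/- 0.02 over 2,000 simulations."""
        rng = np.random.default_rng(2024)
        n_sig = 0
        n_rep = 2000
        for _ in range(n_rep):
            groups = {str(i): rng.normal(size=5) for i in range(4)}
            if one_way_anova(groups).p_value < 0.05:
                n_sig += 1
        assert 0.03 <= n_sig / n_rep <= 0.07


class TestTukey:
    def test_identical_groups_adjusted_p_one(self):
        res = tukey_hsd({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]})
        for r in res:
            assert r.p_value == pytest.approx(1.0, abs=1e-9)

    def test_two_groups_reduces_to_pooled_t(self, rng):
        a, b = rng.normal(size=7), rng.normal(0.8, 1.0, size=5)
        res = tukey_hsd({"a": a, "b": b})[0]
        _, t_p = sps.ttest_ind(a, b, equal_var=True)
        assert res.p_value == pytest.approx(t_p, abs=1e-6)

    def test_matches_reference_implementation(self):
        ours = {tuple(sorted(r.pair)): r.p_value for r in tukey_hsd(TOY)}
        ref = sps.tukey_hsd(*TOY.values())
        names = list(TOY)
        for i in range(3):
            for j in range(i + 1, 3):
                key = tuple(sorted((names[i], names[j])))
                assert ours[key] == pytest.approx(ref.pvalue[i, j], abs=1e-6), key

    def test_family_adjustment_never_below_lsd_t(self):
        """Tukey's adjusted p dominates the unadjusted pairwise comparison
        built on the same pooled error (Fisher LSD: t = q/sqrt(2), n-k df)."""
        res = tukey_hsd(TOY)
        n, k = sum(len(v) for v in TOY.values()), len(TOY)
        for r in res:
            t_p = 2 * sps.t.sf(r.statistic / np.sqrt(2), n - k)
            assert r.p_value >= t_p - 1e-9


class TestPearson:
    def test_affine_relation_gives_unit_correlation(self):
        x = np.arange(10.0)
        assert pearson_corr(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_corr(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_hand_computation(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 3.0, 3.5, 6.0, 8.0])
        xc, yc = x - x.mean(), y - y.mean()
        manual = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        res = pearson_corr(x, y)
        assert res.statistic == pytest.approx(manual, abs=1e-12)
        ref = sps.pearsonr(x, y)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPartialCorrelation:
    def test_collinear_with_covariate_rejected(self, rng):
        z = rng.normal(size=20)
        with pytest.raises(ValueError, match="collinear|degenerate"):
            partial_corr_given(z, rng.normal(size=20), z)

    def test_null_partial_correlation_near_zero(self):
        rng = np.random.default_rng(7)
        n = 400
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = z + rng.normal(size=n)
        res = partial_corr_given(x, y, z)
        assert abs(res.statistic) < 3 / np.sqrt(n)

    def test_residual_method_equals_closed_form(self, rng):
        """Residual-on-residual correlation equals the textbook closed form
        on 100 random instances."""
        for _ in range(100):
            n = 50
            z = rng.normal(size=n)
            x = 0.5 * z + rng.normal(size=n)
            y = -0.3 * z + rng.normal(size=n)
            r_xy = pearson_corr(x, y).statistic
            r_xz = pearson_corr(x, z).statistic
            r_yz = pearson_corr(y, z).statistic
            closed = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
            assert partial_corr_given(x, y, z).statistic == pytest.approx(closed, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n = 40
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = 0.5 * z + rng.normal(size=n)
        ref = pingouin.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        res = partial_corr_given(x, y, z)
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)


class TestWelch:
    def test_identical_groups(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_variances_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([2.0, 2.0, 2.0], [5.0, 5.0])

    def test_matches_reference_implementation(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(0.7, 2.0, size=12)
        res = welch_t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-8)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-8)


class TestGroupedScores:
    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            GroupedScores({"a": [], "b": [1.0]})

    def test_anova_needs_two_groups(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0, 2.0]})
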