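"""Group tests, Bonferroni, regressions, ANCOVA, and power."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from grsgdm.stats import (ancova_gs_by_group, bonferroni,
                          glucose_on_gs_regression, power_variance_explained,
                          table4_like, two_group_test)


class TestTwoGroupTest:
    def test_identical_samples_t_zero_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = two_group_test(x, x, test="t_test")
        assert res.statistic == pytest.approx(0.0) and res.p_raw == pytest.approx(1.0)

    def test_zero_variance_identical_groups(self):
        res = two_group_test([5.0, 5.0], [5.0, 5.0], test="t_test")
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        a = two_group_test(x, y)
        b = two_group_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_raw == pytest.approx(b.p_raw)

    def test_pooled_vs_welch_differ_with_unequal_variances(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 5, 40)
        pooled = two_group_test(x, y, welch=False)
        welch = two_group_test(x, y, welch=True)
        assert pooled.p_raw != pytest.approx(welch.p_raw, rel=1e-6)

    def test_rank_sum_matches_exhaustive_permutation(self):
        """Exact rank-sum p vs full enumeration of all C(12,6) labelings."""
        x = [1.2, 3.4, 2.2, 5.1, 0.7, 4.0]
        y = [2.9, 6.3, 7.1, 5.8, 8.2, 4.4]
        res = two_group_test(x, y, test="wilcoxon")
        pooled = np.array(x + y)
        ranks = sps.rankdata(pooled)
        w_obs = ranks[:6].sum()
        n = len(pooled)
        ws = np.array([ranks[list(idx)].sum()
                       for idx in combinations(range(n), 6)])
        mu = ws.mean()
        p_perm = np.mean(np.abs(ws - mu) >= abs(w_obs - mu) - 1e-9)
        assert res.p_raw == pytest.approx(p_perm, abs=0.02)

    def test_rank_sum_large_sample_uses_normal_approx(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 50), rng.normal(0.8, 1, 60)
        res = two_group_test(x, y, test="wilcoxon")
        assert 0 <= res.p_raw < 0.01

    def test_small_group_precondition(self):
        with pytest.raises(ValueError):
            two_group_test([1.0], [2.0, 3.0], test="t_test")


class TestBonferroni:
    def test_examples(self):
        assert bonferroni(0.002, 24) == pytest.approx(0.048)
        assert bonferroni(0.1, 16) == 1.0

    @given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 100),
           st.integers(1, 100))
    def test_monotone_in_both_arguments(self, p1, p2, m1, m2):
        lo_p, hi_p = sorted([p1, p2])
        lo_m, hi_m = sorted([m1, m2])
        assert bonferroni(lo_p, lo_m) <= bonferroni(hi_p, lo_m)
        assert bonferroni(lo_p, lo_m) <= bonferroni(lo_p, hi_m)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


class TestRegression:
    def test_exact_linear_fit_recovers_slope(self):
        gs = np.arange(30, dtype=float)
        y = 4.5 + 0.03 * gs
        res = glucose_on_gs_regression(y, gs)
        assert res.beta == pytest.approx(0.03, abs=1e-10)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-8)

    def test_adjustment_covariates_recorded(self):
        rng = np.random.default_rng(3)
        gs = rng.normal(15, 3, 200)
        other = rng.normal(7, 1.5, 200)
        y = 4.5 + 0.03 * gs + 0.2 * other + rng.normal(0, 0.3, 200)
        res = glucose_on_gs_regression(y, gs, adjust_for={"glu_1h": other},
                                       predictor_name="fpg_gs")
        assert res.covariates == ("glu_1h",)
        assert res.ci_low <= res.beta <= res.ci_high

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(4)
        gs = rng.normal(0, 1, 50)
        with pytest.raises(ValueError, match="collinear"):
            glucose_on_gs_regression(rng.normal(0, 1, 50), gs,
                                     adjust_for={"dup": 2 * gs + 1})

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        gs = rng.normal(15, 3, 100)
        y = 4.5 + 0.03 * gs + rng.normal(0, 0.3, 100)
        a = glucose_on_gs_regression(y, gs)
        perm = rng.permutation(100)
        b = glucose_on_gs_regression(y[perm], gs[perm])
        assert a.beta == pytest.approx(b.beta)
        assert a.p_raw == pytest.approx(b.p_raw)

    def test_t_test_equals_binary_predictor_regression(self):
        """Algebraic identity: pooled two-sample t == OLS on a 0/1 dummy."""
        rng = np.random.default_rng(6)
        x, y = rng.normal(16, 3, 40), rng.normal(15, 3, 80)
        t_res = two_group_test(x, y, test="t_test")
        dummy = np.r_[np.ones(40), np.zeros(80)]
        reg = glucose_on_gs_regression(np.r_[x, y], dummy)
        assert t_res.p_raw == pytest.approx(reg.p_raw, rel=1e-9)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="too small"):
            glucose_on_gs_regression([1.0, 2.0], [1.0, 2.0])


class TestAncova:
    def test_independent_covariate_barely_moves_p(self):
        rng = np.random.default_rng(7)
        n = 400
        group = np.r_[np.ones(100), np.zeros(300)]
        gs = 15 + 1.0 * group + rng.normal(0, 3, n)
        cov = rng.normal(25, 4, n)  # independent of group and gs
        unadj = ancova_gs_by_group(gs, group)
        adj = ancova_gs_by_group(gs, group, covariates={"bmi": cov})
        assert np.log10(adj.p_raw) == pytest.approx(np.log10(unadj.p_raw), abs=0.5)

    def test_group_recoded_covariate_collinear(self):
        group = np.r_[np.ones(20), np.zeros(20)]
        gs = np.random.default_rng(8).normal(15, 3, 40)
        with pytest.raises(ValueError, match="collinear"):
            ancova_gs_by_group(gs, group, covariates={"recode": 3 * group - 1})

    def test_constant_group_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ancova_gs_by_group([1.0, 2.0], [1, 1])

    def test_type_i_error_calibrated_under_null(self):
        """No group effect: rejection rate over replicates ~ alpha."""
        rng = np.random.default_rng(9)
        n, reps, alpha = 60, 1000, 0.05
        group = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        rejections = 0
        for _ in range(reps):
            gs = rng.normal(15, 3, n)
            cov = rng.normal(25, 4, n)
            res = ancova_gs_by_group(gs, group, covariates={"bmi": cov})
            rejections += res.p_raw < alpha
        rate = rejections / reps
        assert rate == pytest.approx(alpha, abs=3 * np.sqrt(alpha * 0.95 / reps))


class TestPower:
    def test_stated_design_reaches_full_power(self):
        assert power_variance_explained(2628, 0.06, 0.002) == pytest.approx(
            1.0, abs=0.005)

    def test_null_power_equals_size(self):
        for alpha in (0.05, 0.002):
            assert power_variance_explained(500, 0.0, alpha) == alpha

    def test_monotone_in_n_and_r2(self):
        grid_n = [10, 50, 200, 1000]
        powers_n = [power_variance_explained(n, 0.03, 0.05) for n in grid_n]
        assert powers_n == sorted(powers_n)
        grid_r2 = [0.005, 0.02, 0.06, 0.2]
        powers_r = [power_variance_explained(100, r, 0.05) for r in grid_r2]
        assert powers_r == sorted(powers_r)

    def test_against_monte_carlo_at_external_study_size(self):
        """Analytic noncentral-F power vs simulated slope tests at n = 849."""
        n, r2, alpha, reps = 849, 0.06, 0.002, 4000
        analytic = power_variance_explained(n, r2, alpha)
        rng = np.random.default_rng(10)
        rho = np.sqrt(r2)
        rejections = 0
        for start in range(0, reps, 500):
            k = min(500, reps - start)
            x = rng.standard_normal((n, k))
            y = rho * x + np.sqrt(1 - r2) * rng.standard_normal((n, k))
            xc = x - x.mean(0)
            yc = y - y.mean(0)
            r = (xc * yc).sum(0) / np.sqrt((xc**2).sum(0) * (yc**2).sum(0))
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p = 2 * sps.t.sf(np.abs(t), n - 2)
            rejections += (p < alpha).sum()
        mc = rejections / reps
        assert analytic == pytest.approx(mc, abs=3 * np.sqrt(mc * (1 - mc) / reps) + 0.005)


def test_table4_like_grid_shape(small_cohort, small_cohort_scores):
    cfg, cohort = small_cohort
    t4 = table4_like(cohort.phenotypes, small_cohort_scores)
    assert len(t4) == 12  # 3 measures x 2 scores x 2 adjustments
    unadj_fast = t4[(t4.glucose_measure == "Fasting") & (t4.score == "FPG_GS")
                    & ~t4.adjusted_for_other_glucose]
    assert unadj_fast.iloc[0]["beta"] > 0
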