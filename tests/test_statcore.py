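"""Unit and property tests for the shared estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adgwas import statcore
from adgwas.statcore import SingularDesignError

from conftest import expand_2x2


class TestLogisticFit:
    @pytest.mark.parametrize("table", [(10, 5, 5, 10), (20, 7, 11, 13),
                                       (50, 30, 25, 40), (8, 12, 9, 6)])
    def test_matches_2x2_closed_form(self, table):
        """On a 2x2-expandable design the MLE equals ln(ad/bc) with the
        classical variance 1/a+1/b+1/c+1/d."""
        a, b, c, d = table
        design, outcome = expand_2x2(a, b, c, d)
        fit = statcore.logistic_fit(design, outcome)
        assert fit.converged
        assert fit.coefficients[1] == pytest.approx(math.log(a * d / (b * c)), abs=1e-6)
        assert fit.standard_errors[1] == pytest.approx(
            math.sqrt(1 / a + 1 / b + 1 / c + 1 / d), abs=1e-6)

    def test_intercept_only_is_logit_prevalence(self):
        y = np.array([1.0] * 30 + [0.0] * 70)
        fit = statcore.logistic_fit(np.ones((100, 1)), y)
        assert fit.coefficients[0] == pytest.approx(math.log(30 / 70), abs=1e-8)

    def test_null_covariate_z_is_calibrated(self, rng):
        for _ in range(20):
            x = np.column_stack([np.ones(10_000), rng.standard_normal(10_000)])
            y = rng.binomial(1, 0.4, 10_000).astype(float)
            fit = statcore.logistic_fit(x, y)
            assert abs(fit.z_values()[1]) < 4

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = np.column_stack([np.ones(500), rng.standard_normal((500, 3))])
        y = rng.binomial(1, 1 / (1 + np.exp(-x[:, 1] + 0.3)), 500).astype(float)
        ours = statcore.logistic_fit(x, y)
        ref = sm.Logit(y, x).fit(disp=0)
        np.testing.assert_allclose(ours.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.standard_errors, ref.bse, atol=1e-6)
        assert ours.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_perfect_separation_flags_non_convergence(self):
        x = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
        y = np.r_[np.zeros(10), np.ones(10)]
        fit = statcore.logistic_fit(x, y)
        assert not fit.converged

    def test_constant_column_raises(self):
        x = np.column_stack([np.ones(20), np.full(20, 3.0)])
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(SingularDesignError):
            statcore.logistic_fit(x, y)

    def test_se_is_sqrt_of_covariance_diagonal(self, rng):
        x = np.column_stack([np.ones(300), rng.standard_normal((300, 2))])
        y = rng.binomial(1, 0.5, 300).astype(float)
        fit = statcore.logistic_fit(x, y)
        np.testing.assert_allclose(fit.standard_errors,
                                   np.sqrt(np.diag(fit.covariance)))


class TestWaldOrCi:
    def test_unit_beta_free_interval(self):
        or_, lo, hi = statcore.wald_or_ci(0.0, 0.1, 0.95)
        assert (or_, lo, hi) == pytest.approx((1.0, 0.822, 1.217), abs=5e-4)

    def test_reconstructs_printed_confidence_interval(self):
        or_, lo, hi = statcore.wald_or_ci(0.0677, 0.0120, 0.95)
        assert (or_, lo, hi) == pytest.approx((1.070, 1.045, 1.095), abs=1e-3)

    def test_zero_se_collapses_interval(self):
        or_, lo, hi = statcore.wald_or_ci(0.3, 0.0, 0.95)
        assert lo == or_ == hi == pytest.approx(math.exp(0.3))

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            statcore.wald_or_ci(0.0, -0.1, 0.95)


class TestWilcoxon:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [4, 5, 6], 2 / 20),   # all C(6,3) assignments enumerated
        ([1, 2], [3, 4], 2 / 6),
    ])
    def test_exact_small_sample_p(self, x, y, expected):
        res = statcore.wilcoxon_rank_sum(x, y)
        assert res.mode == "exact"
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        res = statcore.wilcoxon_rank_sum([3, 1, 2, 2], [1, 2, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_constant_samples_flagged(self):
        res = statcore.wilcoxon_rank_sum([5, 5, 5], [5, 5])
        assert res.degenerate and res.p_value == 1.0

    def test_normal_approximation_tracks_exact(self, rng):
        """In the size regime where the approximation is auto-selected
        (n1 + n2 > 12), tie-free asymptotic p is within 0.02 of exact.
        (Below that the implementation enumerates exactly, and the
        approximation degrades to |diff| ~ 0.09 at the smallest sizes.)"""
        for _ in range(60):
            n1 = int(rng.integers(5, 9))
            n2 = int(rng.integers(max(5, 13 - n1), 9))
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = vals[:n1], vals[n1:]
            p_exact = statcore.wilcoxon_rank_sum(x, y, mode="exact").p_value
            p_asym = statcore.wilcoxon_rank_sum(x, y, mode="asymptotic").p_value
            assert abs(p_exact - p_asym) < 0.02

    def test_statistic_within_achievable_rank_sums(self, rng):
        x, y = rng.normal(size=7), rng.normal(size=5)
        res = statcore.wilcoxon_rank_sum(x, y)
        n1, n = 7, 12
        assert n1 * (n1 + 1) / 2 <= res.statistic <= n1 * (2 * n - n1 + 1) / 2


def _breslow_grid_oracle(times, event, x, grid):
    """Brute-force 1-D maximizer of the Breslow log partial likelihood."""
    def ll(b):
        order = np.argsort(-np.asarray(times, float), kind="stable")
        t, e, xs = (np.asarray(v)[order] for v in (times, event, x))
        r = np.exp(xs * b)
        s0 = np.cumsum(r)
        total, i = 0.0, 0
        while i < len(t):
            j = i
            while j + 1 < len(t) and t[j + 1] == t[i]:
                j += 1
            ev = e[i:j + 1] == 1
            d = ev.sum()
            if d:
                total += float((xs[i:j + 1][ev] * b).sum() - d * math.log(s0[j]))
            i = j + 1
        return total
    vals = [ll(b) for b in grid]
    return grid[int(np.argmax(vals))]


class TestCox:
    def test_two_group_hazard_ratio_recovery(self):
        rng = np.random.default_rng(7)
        g = np.r_[np.zeros(2500), np.ones(2500)]
        t = rng.exponential(1.0 / np.exp(g * math.log(2.0)))
        fit = statcore.cox_ph_fit(t + 1e-9, np.ones(5000), g)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(math.log(2), abs=0.05)

    def test_null_covariate_calibrated(self, rng):
        for _ in range(20):
            t = rng.exponential(1.0, 5000)
            x = rng.standard_normal(5000)
            fit = statcore.cox_ph_fit(t, np.ones(5000), x)
            assert abs(fit.z_values()[0]) < 4

    def test_matches_breslow_grid_oracle(self):
        # covariate pattern must not be monotone in event time, else the
        # partial likelihood has no interior maximum
        times = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4)
        x = np.array([1.0, 0.0, 1.0, 0.0])
        grid = np.linspace(-4, 4, 160_001)
        oracle = _breslow_grid_oracle(times, event, x, grid)
        fit = statcore.cox_ph_fit(times, event, x)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(oracle, abs=1e-4)

    def test_matches_lifelines_without_ties(self):
        # Efron and Breslow coincide on tie-free data
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 400
        x = rng.standard_normal((n, 2))
        t = rng.exponential(1.0 / np.exp(0.5 * x[:, 0]))
        df = pd.DataFrame({"t": t, "e": 1, "x0": x[:, 0], "x1": x[:, 1]})
        ref = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        fit = statcore.cox_ph_fit(t, np.ones(n), x)
        np.testing.assert_allclose(fit.coefficients,
                                   ref.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.standard_errors,
                                   ref.standard_errors_.to_numpy(), atol=1e-5)

    def test_row_permutation_is_bit_identical(self, rng):
        n = 200
        t = np.round(rng.uniform(60, 90, n))  # integer ages force ties
        x = rng.standard_normal((n, 3))
        e = np.ones(n)
        fit1 = statcore.cox_ph_fit(t, e, x)
        perm = rng.permutation(n)
        fit2 = statcore.cox_ph_fit(t[perm], e[perm], x[perm])
        assert np.array_equal(fit1.coefficients, fit2.coefficients)
        assert np.array_equal(fit1.covariance, fit2.covariance)
        assert fit1.log_likelihood == fit2.log_likelihood

    def test_constant_covariate_raises(self):
        with pytest.raises(SingularDesignError):
            statcore.cox_ph_fit([1, 2, 3], [1, 1, 1], np.full(3, 2.0))

    def test_monotone_likelihood_flagged(self):
        # all group-1 events strictly precede all group-0 events
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        fit = statcore.cox_ph_fit(t, np.ones(6), x)
        assert not fit.converged


def _hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact rational enumeration over heterozygote counts (integer weights)."""
    n = n_AA + n_Aa + n_aa
    na = 2 * n_aa + n_Aa
    na = min(na, 2 * n - na)
    if na == 0:
        return 1.0
    weights = {}
    for h in range(na % 2, na + 1, 2):
        rare = (na - h) // 2
        weights[h] = math.comb(n, h) * math.comb(n - h, rare) * 2 ** h
    total = sum(weights.values())
    obs = weights[n_Aa]
    return sum(w for w in weights.values() if w <= obs) / total


class TestHwe:
    def test_monomorphic_returns_one(self):
        assert statcore.hwe_exact_test(0, 0, 50) == 1.0

    def test_equilibrium_table_matches_enumeration(self):
        assert statcore.hwe_exact_test(25, 50, 25) == pytest.approx(
            _hwe_enumeration_oracle(25, 50, 25), rel=1e-9)

    def test_no_het_table_fails_standard_filter(self):
        p = statcore.hwe_exact_test(50, 0, 50)
        assert p == pytest.approx(_hwe_enumeration_oracle(50, 0, 50), rel=1e-9)
        assert p < 1e-4

    def test_symmetric_in_homozygote_classes(self, rng):
        for _ in range(50):
            a, h, b = rng.integers(0, 60, 3)
            if a + h + b == 0:
                continue
            assert statcore.hwe_exact_test(a, h, b) == pytest.approx(
                statcore.hwe_exact_test(b, h, a), rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            statcore.hwe_exact_test(-1, 2, 3)


class TestQuantiles:
    def test_median_of_1_to_100(self):
        qb = statcore.quantile_boundaries(np.arange(1, 101), 2)
        np.testing.assert_allclose(qb.cuts, [50.5])

    def test_quartiles_linear_interpolation(self):
        qb = statcore.quantile_boundaries(np.arange(1, 101), 4)
        np.testing.assert_allclose(qb.cuts, [25.75, 50.5, 75.25])
        # independent route
        np.testing.assert_allclose(
            qb.cuts, np.percentile(np.arange(1, 101), [25, 50, 75]))

    def test_constant_input_degenerate(self):
        qb = statcore.quantile_boundaries(np.full(10, 3.3), 4)
        assert qb.degenerate
        np.testing.assert_allclose(qb.cuts, 3.3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            statcore.quantile_boundaries([], 2)

    @given(st.integers(2, 10), st.integers(50, 300), st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_balanced_bin_occupancy(self, k, n, seed):
        """Tie-free inputs: each bin anchors between floor(n/k) and ceil(n/k)
        of the defining values."""
        vals = np.random.default_rng(seed).permutation(np.linspace(0, 1, n))
        qb = statcore.quantile_boundaries(vals, k)
        bins = np.searchsorted(qb.cuts, vals, side="left")
        counts = np.bincount(bins, minlength=k)
        assert counts.min() >= math.floor(n / k)
        assert counts.max() <= math.ceil(n / k)
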