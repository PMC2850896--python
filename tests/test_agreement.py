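import math

import numpy as np
import pytest
from scipy import stats

from fourcomp.agreement import (
    agreement_report,
    bland_altman,
    correlate_differences,
    detectable_correlation,
    identity_regression,
    moment_loa,
    one_sample_vs_reference,
    paired_comparison,
    r_squared_percent,
)


class TestPairedComparison:
    def test_identical_vectors(self):
        stat, p, name = paired_comparison([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert stat == 0.0 and p == 1.0 and name == "paired_t"

    def test_constant_nonzero_difference_degenerate(self):
        x = np.array([2.0, 3, 4, 5, 6])
        with pytest.raises(ValueError, match="zero variance"):
            paired_comparison(x, x - 1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_comparison([1, 2, 3], [1, 2])

    def test_normality_gate_switches_to_wilcoxon(self, rng):
        y = rng.normal(0, 1, 40)
        x = y + rng.exponential(1.0, 40) ** 3  # heavily skewed differences
        _, _, name = paired_comparison(x, y)
        assert name == "wilcoxon"

    def test_against_sign_flip_permutation_oracle(self, rng):
        n = 27
        d = rng.normal(0.5, 1.0, n)
        x = rng.normal(10, 2, n)
        y = x - d
        _, p_t, name = paired_comparison(x, y)
        if name != "paired_t":  # rare unlucky draw; the oracle targets the t branch
            pytest.skip("normality gate rejected this draw")
        signs = rng.choice([-1.0, 1.0], size=(20000, n))
        perm_means = (signs * d).mean(axis=1)
        p_perm = np.mean(np.abs(perm_means) >= abs(d.mean()))
        assert p_t == pytest.approx(p_perm, abs=0.02)


class TestOneSample:
    def test_mean_equals_reference(self):
        x = np.array([1.0, 2.0, 3.0])
        t, p = one_sample_vs_reference(x, 2.0)
        assert t == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_hand_arithmetic(self, rng):
        # mean 0.72, sd 0.02, n 27 vs ref 0.7382 -> |t| = 0.0182/(0.02/sqrt(27))
        z = rng.standard_normal(27)
        z = (z - z.mean()) / z.std(ddof=1)
        x = 0.72 + 0.02 * z
        t, _ = one_sample_vs_reference(x, 0.7382)
        assert abs(t) == pytest.approx(0.0182 / (0.02 / math.sqrt(27)), rel=1e-9)

    def test_joint_scaling_invariance(self, rng):
        x = rng.normal(5, 1, 20)
        t1, _ = one_sample_vs_reference(x, 4.0)
        t2, _ = one_sample_vs_reference(10 * x, 40.0)
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            one_sample_vs_reference([2.0, 2.0, 2.0], 1.0)


class TestIdentityRegression:
    def test_identity_data(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        reg = identity_regression(x, x)
        assert reg.slope == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(0.0)
        assert reg.r == pytest.approx(1.0)
        assert reg.see == 0.0
        assert reg.slope_p_vs_1 == 1.0
        assert reg.intercept_p_vs_0 == 1.0

    def test_exact_double_slope(self):
        x = np.array([1.0, 2.0, 3.0])
        reg = identity_regression(2 * x, x)
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.see == pytest.approx(0.0, abs=1e-12)
        assert reg.slope_p_vs_1 == 0.0  # exact fit, slope != 1: below numeric floor

    def test_offset_gives_unit_slope_and_intercept_c(self, rng):
        x = rng.normal(10, 3, 30)
        reg = identity_regression(x + 2.5, x)
        assert reg.slope == pytest.approx(1.0, abs=1e-9)
        assert reg.intercept == pytest.approx(2.5, abs=1e-9)

    def test_against_normal_equations_oracle(self, rng):
        n = 27
        x = rng.normal(10, 2, n)
        y = 0.8 * x + rng.normal(0, 1.5, n)
        reg = identity_regression(y, x)
        # brute-force normal equations
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        see = math.sqrt(resid @ resid / (n - 2))
        assert reg.intercept == pytest.approx(beta[0], abs=1e-10)
        assert reg.slope == pytest.approx(beta[1], abs=1e-10)
        assert reg.see == pytest.approx(see, abs=1e-10)
        # slope t-test vs 1 recomputed from scratch
        se_slope = see / math.sqrt(((x - x.mean()) ** 2).sum())
        p = 2 * stats.t.sf(abs((beta[1] - 1) / se_slope), n - 2)
        assert reg.slope_p_vs_1 == pytest.approx(p, abs=1e-12)

    def test_zero_predictor_variance(self):
        with pytest.raises(ValueError):
            identity_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestRSquaredPercent:
    @pytest.mark.parametrize("r, expected", [(0.0, 0), (0.60, 36), (0.62, 38), (-0.53, 28)])
    def test_values(self, r, expected):
        assert r_squared_percent(r) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            r_squared_percent(1.2)


class TestBlandAltman:
    def test_identical_methods(self):
        a = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(a, a)
        assert ba.bias == 0.0
        assert (ba.loa_lower, ba.loa_upper) == (0.0, 0.0)
        assert not ba.trend_computable
        assert math.isnan(ba.trend_r)

    def test_hand_example(self):
        # diffs {-1, 0, 1} against means {1, 2, 3}
        m = np.array([1.0, 2.0, 3.0])
        d = np.array([-1.0, 0.0, 1.0])
        ba = bland_altman(m + d / 2, m - d / 2)
        assert ba.bias == pytest.approx(0.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.loa_lower == pytest.approx(-1.96)
        assert ba.loa_upper == pytest.approx(1.96)
        assert ba.trend_r == pytest.approx(1.0)

    def test_loa_midpoint_is_bias(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(0.3, 1.4, 50)
        ba = bland_altman(a, b)
        assert (ba.loa_lower + ba.loa_upper) / 2 == pytest.approx(ba.bias, abs=1e-12)
        assert ba.loa_upper - ba.loa_lower == pytest.approx(2 * 1.96 * ba.sd_diff)

    def test_matches_moment_loa_on_sample_moments(self, rng):
        a = rng.normal(-0.4, 1.1, 200)
        b = rng.normal(-1.2, 2.7, 200)
        ba = bland_altman(a, b)
        r_ab = np.corrcoef(a, b)[0, 1]
        bias, lo, hi = moment_loa(a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1), r_ab)
        assert ba.bias == pytest.approx(bias, abs=1e-10)
        assert ba.loa_lower == pytest.approx(lo, abs=1e-10)
        assert ba.loa_upper == pytest.approx(hi, abs=1e-10)

    def test_negation_symmetry(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 2, 40)
        ba1 = bland_altman(a, b)
        ba2 = bland_altman(-a, -b)
        assert abs(ba2.bias) == pytest.approx(abs(ba1.bias))
        assert abs(ba2.trend_r) == pytest.approx(abs(ba1.trend_r))
        assert ba2.trend_p == pytest.approx(ba1.trend_p)


class TestMomentLoa:
    def test_identical_moments_perfect_correlation(self):
        assert moment_loa(1.0, 2.0, 1.0, 2.0, 1.0) == (0.0, 0.0, 0.0)

    def test_printed_change_moments(self):
        # frozen from the closed form with the change-score moments and r=0.53
        bias, lo, hi = moment_loa(-0.41, 1.05, -1.22, 2.70, 0.53)
        assert bias == pytest.approx(0.81)
        assert hi == pytest.approx(5.3593, abs=1e-3)
        assert lo == pytest.approx(-3.7393, abs=1e-3)

    def test_anticorrelation_maximal_disagreement(self):
        bias, lo, hi = moment_loa(0.0, 1.0, 0.0, 2.0, -1.0)
        assert hi == pytest.approx(1.96 * 3.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            moment_loa(0, 0, 0, 1, 0.5)
        with pytest.raises(ValueError):
            moment_loa(0, 1, 0, 1, 1.5)


class TestDetectableCorrelation:
    def test_study_parameters(self):
        assert round(detectable_correlation(27, 0.05, 0.80), 2) == 0.51

    def test_uncorrected_form(self):
        r = detectable_correlation(27, 0.05, 0.80, bias_correction=False)
        assert r == pytest.approx(math.tanh(
            (stats.norm.ppf(0.975) + stats.norm.ppf(0.80)) / math.sqrt(24)
        ), abs=1e-9)

    def test_decreasing_in_n(self):
        rs = [detectable_correlation(n) for n in (10, 27, 100, 1000)]
        assert all(a > b for a, b in zip(rs, rs[1:]))

    def test_increasing_in_power(self):
        assert detectable_correlation(27, power=0.9) > detectable_correlation(27, power=0.7)

    def test_half_power_limit(self):
        # at power 0.5 and large n, r_min ~ z_{0.975}/sqrt(n-3)
        n = 5000
        r = detectable_correlation(n, 0.05, 0.5, bias_correction=False)
        assert r == pytest.approx(stats.norm.ppf(0.975) / math.sqrt(n - 3), rel=1e-3)

    def test_domain(self):
        with pytest.raises(ValueError):
            detectable_correlation(3)
        with pytest.raises(ValueError):
            detectable_correlation(27, alpha=1.5)


class TestCorrelateDifferences:
    def test_constant_covariate_not_computable(self):
        r, p = correlate_differences([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert math.isnan(r) and math.isnan(p)

    def test_self_correlation(self):
        r, _ = correlate_differences([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r == pytest.approx(1.0)

    def test_null_p_values_uniform(self, rng):
        # under independence the p-values are Uniform(0,1): KS over 500 reps
        ps = []
        for _ in range(500):
            _, p = correlate_differences(rng.normal(0, 1, 20), rng.normal(0, 1, 20))
            ps.append(p)
        ks_p = stats.kstest(ps, "uniform").pvalue
        assert ks_p > 1e-3


class TestAgreementReport:
    def test_all_p_values_in_unit_interval(self, rng):
        a = rng.normal(0, 1, 30)
        b = 0.8 * a + rng.normal(0, 0.5, 30)
        rep = agreement_report(a, b)
        for name in ("trend_p", "slope_p_vs_1", "intercept_p_vs_0", "mean_comparison_p"):
            val = getattr(rep, name)
            assert 0.0 <= val <= 1.0

    def test_perfect_method(self):
        a = np.array([5.0, 6.0, 7.0, 8.0])
        rep = agreement_report(a, a)
        assert rep.bias == 0.0
        assert rep.loa_lower == rep.loa_upper == 0.0
        assert rep.slope == pytest.approx(1.0)
        assert rep.intercept == pytest.approx(0.0)
        assert rep.mean_comparison_p == 1.0
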