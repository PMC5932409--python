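import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lgcpower import (
    GrowthParams,
    StudyDesign,
    analytic_power,
    critical_value,
    ecr,
    effective_error,
    noncentrality_approx,
    noncentrality_from_ecr,
    power_from_lambda,
    satorra_saris_lambda,
    TestSpec as SlopeTestSpec,
)


class TestNoncentrality:
    def test_zero_ecr_gives_zero(self):
        assert noncentrality_from_ecr(0.0, 250) == 0.0

    def test_direct_evaluation(self):
        # ECR = 2/7 (five annual occasions scenario), N = 100
        assert noncentrality_from_ecr(2.0 / 7.0, 100) == pytest.approx(6.3528, abs=1e-3)

    def test_linear_in_n(self):
        lam1 = noncentrality_from_ecr(0.4, 100)
        lam2 = noncentrality_from_ecr(0.4, 200)
        assert lam2 == pytest.approx(2 * lam1)

    def test_increasing_and_convex_in_ecr(self):
        grid = np.linspace(0, 0.95, 40)
        vals = np.array([noncentrality_from_ecr(r, 1) for r in grid])
        assert np.all(np.diff(vals) > 0)
        assert np.all(np.diff(vals, 2) > 0)

    def test_ecr_of_one_rejected(self):
        with pytest.raises(ValueError):
            noncentrality_from_ecr(1.0, 100)


class TestNoncentralityApprox:
    def test_printed_formula_verbatim(self):
        assert noncentrality_approx(0.0, 100) == 0.0
        assert noncentrality_approx(2.0 / 7.0, 100) == pytest.approx(11.4286, abs=1e-3)

    def test_ratio_to_exact_tends_to_two_at_small_ecr(self):
        # exact expands as ECR^2/2 + O(ECR^3); the printed form as ECR^2
        for r in (1e-3, 1e-4):
            ratio = noncentrality_approx(r, 1) / noncentrality_from_ecr(r, 1)
            assert ratio == pytest.approx(2.0, rel=5e-3)


class TestSatorraSaris:
    def test_no_misfit_under_null(self, annual_design):
        p = GrowthParams(var_intercept=10, var_slope=0, var_residual=50)
        assert satorra_saris_lambda(annual_design, p, "specific_1df",
                                    n_subjects=100) == pytest.approx(0.0, abs=1e-12)

    def test_matches_minimal_model_identity(self, annual_design, annual_params):
        lam = satorra_saris_lambda(annual_design, annual_params, "specific_1df",
                                   nuisance_policy="fixed_true", n_subjects=100)
        rel = ecr(1.0, effective_error(annual_design, 10, 50))
        assert lam == pytest.approx(noncentrality_from_ecr(rel, 100), abs=1e-6 * 100)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(
        times=st.lists(st.floats(-3, 8), min_size=3, max_size=6, unique=True)
        .map(sorted).filter(lambda ts: all(b - a > 0.1 for a, b in zip(ts, ts[1:]))),
        var_i=st.floats(0.5, 50), var_s=st.floats(0.05, 5), var_e=st.floats(1, 60),
    )
    def test_power_equivalence_identity_randomized(self, times, var_i, var_s, var_e):
        """Central coherence: the full-model lambda equals the minimal-model lambda."""
        d = StudyDesign(times)
        p = GrowthParams(var_intercept=var_i, var_slope=var_s, var_residual=var_e)
        n = 100
        lam_full = satorra_saris_lambda(d, p, "specific_1df",
                                        nuisance_policy="fixed_true", n_subjects=n)
        rel = ecr(var_s, effective_error(d, var_i, var_e))
        assert lam_full == pytest.approx(noncentrality_from_ecr(rel, n), abs=1e-6 * n)

    def test_generalized_test_dominates_specific_under_covariance(self, annual_design):
        p = GrowthParams.with_correlation(
            var_intercept=10, var_slope=1, intercept_slope_correlation=0.5,
            var_residual=50,
        )
        lam2 = satorra_saris_lambda(annual_design, p, "generalized_2df", n_subjects=100)
        lam1 = satorra_saris_lambda(annual_design, p, "specific_1df", n_subjects=100)
        assert lam2 >= lam1 - 1e-9

    def test_free_nuisance_never_exceeds_fixed(self, annual_design, annual_params):
        fixed = satorra_saris_lambda(annual_design, annual_params, "specific_1df",
                                     nuisance_policy="fixed_true", n_subjects=100)
        free = satorra_saris_lambda(annual_design, annual_params, "specific_1df",
                                    nuisance_policy="free", n_subjects=100)
        assert free <= fixed + 1e-8


class TestPowerFromLambda:
    def test_null_case_returns_alpha(self):
        assert power_from_lambda(0.0, 1, 0.05) == pytest.approx(0.05)
        assert power_from_lambda(0.0, 2, 0.10) == pytest.approx(0.10)

    def test_reference_value(self):
        assert power_from_lambda(6.353, 1, 0.05) == pytest.approx(0.712, abs=5e-3)

    def test_agrees_with_simulated_noncentral_draws(self):
        lam, df, alpha, n = 6.353, 1, 0.05, 100_000
        rng = np.random.default_rng(99)
        draws = stats.ncx2.rvs(df, lam, size=n, random_state=rng)
        crit = stats.chi2.ppf(1 - alpha, df)
        empirical = np.mean(draws > crit)
        se = np.sqrt(empirical * (1 - empirical) / n)
        assert power_from_lambda(lam, df, alpha) == pytest.approx(empirical, abs=3 * se)

    def test_tends_to_one(self):
        assert power_from_lambda(500.0, 1, 0.05) > 0.9999

    def test_boundary_mixture_beats_plain_reference(self):
        for lam in (1.0, 5.0, 10.0):
            assert power_from_lambda(lam, 1, 0.05, "boundary_mixture") \
                > power_from_lambda(lam, 1, 0.05, "plain_chisq")

    def test_mixture_critical_values(self):
        # df=1: 50:50 point mass at 0 and chi2(1)
        assert critical_value(1, 0.05, "boundary_mixture") == pytest.approx(
            stats.chi2.ppf(0.90, 1)
        )
        # df=2: 50:50 chi2(1) and chi2(2); tail probability alpha at the root
        c = critical_value(2, 0.05, "boundary_mixture")
        assert 0.5 * stats.chi2.sf(c, 1) + 0.5 * stats.chi2.sf(c, 2) == pytest.approx(0.05)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            critical_value(3, 0.05)


class TestAnalyticPower:
    def test_full_chain_five_annual_occasions(self, annual_design, annual_params):
        est = analytic_power(annual_design, annual_params, n_subjects=100)
        assert est.power == pytest.approx(0.712, abs=5e-3)
        assert est.noncentrality == pytest.approx(6.3528, abs=1e-3)
        assert est.method == "analytic"

    def test_null_scenario_power_is_alpha(self, annual_design):
        p = GrowthParams(var_intercept=10, var_slope=0, var_residual=50)
        est = analytic_power(annual_design, p, n_subjects=100, alpha=0.05)
        assert est.power == pytest.approx(0.05, abs=1e-9)

    def test_increasing_in_sample_size(self, annual_design, annual_params):
        powers = [analytic_power(annual_design, annual_params, n).power
                  for n in (50, 100, 200, 400)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_routes_through_satorra_saris_for_nonzero_covariance(self, annual_design):
        p = GrowthParams.with_correlation(
            var_intercept=10, var_slope=1, intercept_slope_correlation=0.5,
            var_residual=50,
        )
        est2 = analytic_power(annual_design, p, 100, test="generalized_2df")
        est0 = analytic_power(
            annual_design,
            GrowthParams(var_intercept=10, var_slope=1, var_residual=50),
            100, test="generalized_2df",
        )
        assert est2.power > est0.power  # covariance adds detectable signal

    def test_wald_not_supported_analytically(self, annual_design, annual_params):
        with pytest.raises(ValueError):
            analytic_power(annual_design, annual_params, 100, test="wald")


class TestSlopeTestSpec:
    def test_df_follows_kind(self):
        assert SlopeTestSpec("specific_1df").df == 1
        assert SlopeTestSpec("generalized_2df").df == 2

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            SlopeTestSpec("specific_1df", alpha=0.0)
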