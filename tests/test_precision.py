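import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lgcpower import (
    GrowthParams,
    StudyDesign,
    center_design,
    ecr,
    effective_error,
    generalized_ecr,
    grr,
    icc2,
    precision_summary,
    scale_design,
    shift_design,
    sst,
)


class TestEffectiveError:
    @pytest.mark.parametrize(
        "times, var_i, var_e, expected",
        [
            ([0, 1, 2, 3, 4], 10, 50, 2.50),          # five annual occasions
            ([0, 0.25, 0.5, 0.75, 1], 90, 5.9, 9.20),  # quarterly, precise instrument
            ([0, 0.25, 0.5, 0.75, 1], 90, 10, 15.33),  # quarterly, noisier instrument
            ([0, 2.5, 5], 90, 10, 0.76),               # three occasions over 5 years
        ],
    )
    def test_worked_examples(self, times, var_i, var_e, expected):
        value = effective_error(StudyDesign(times), var_i, var_e)
        assert round(value, 2) == pytest.approx(expected)

    def test_centered_design_reduces_to_residual_over_sum_t2(self):
        # sum of times is 0, so eta drops out: 50 / 10
        assert effective_error(StudyDesign([-2, -1, 0, 1, 2]), 10, 50) == pytest.approx(5.0)

    def test_zero_intercept_variance_sets_eta_to_zero(self):
        assert effective_error(StudyDesign([0, 1, 2, 3, 4]), 0, 50) == pytest.approx(50 / 30)

    def test_positive_residual_required(self):
        with pytest.raises(ValueError):
            effective_error(StudyDesign([0, 1, 2]), 10, 0)


class TestICC2:
    def test_worked_example(self):
        assert icc2(10, 50, 5) == pytest.approx(0.5)

    def test_limits(self):
        assert icc2(0, 30, 4) == 0.0
        assert icc2(12, 0, 4) == 1.0

    def test_equals_eta_times_m(self, annual_design, annual_params):
        s = precision_summary(annual_design, annual_params)
        assert s.icc2 == pytest.approx(s.eta * annual_design.n_occasions)


class TestSST:
    def test_hand_arithmetic(self):
        assert sst(StudyDesign([0, 2.5, 5])) == (pytest.approx(12.5), pytest.approx(2.5))

    def test_rearranged_occasions(self):
        s, _ = sst(StudyDesign([0, 1, 3, 3.5, 4]))
        assert s == pytest.approx(11.8)


class TestReliabilities:
    def test_ecr_worked_examples(self):
        assert round(ecr(1.35, 0.7593), 2) == pytest.approx(0.64)
        assert round(ecr(1.0, 2.50), 2) == pytest.approx(0.29)
        assert ecr(0.0, 3.0) == 0.0

    def test_grr_worked_examples(self):
        assert round(grr(1.35, 10, 12.5), 2) == pytest.approx(0.63)
        assert round(grr(1.0, 50, 10), 2) == pytest.approx(0.17)

    def test_grr_is_shift_invariant(self, annual_design, annual_params):
        shifted = shift_design(annual_design, 7.3)
        for d in (annual_design, shifted):
            s, _ = sst(d)
            assert grr(1.0, 50.0, s) == pytest.approx(grr(1.0, 50.0, annual_design.sst))

    def test_zero_sst_rejected(self):
        with pytest.raises(ValueError):
            grr(1.0, 50.0, 0.0)


class TestPrecisionSummary:
    def test_internally_consistent(self, annual_design, annual_params):
        s = precision_summary(annual_design, annual_params)
        assert s.ecr == pytest.approx(1.0 / (1.0 + s.effective_error), rel=1e-12)
        assert s.dispersion * (annual_design.n_occasions - 1) == pytest.approx(s.sst)
        assert s.effective_error == pytest.approx(2.50)
        assert round(s.ecr, 2) == pytest.approx(0.29)
        assert round(s.grr, 2) == pytest.approx(0.17)
        assert s.icc2 == pytest.approx(0.5)

    def test_consistency_holds_with_nonzero_covariance(self):
        d = StudyDesign([0, 1, 2, 3])
        p = GrowthParams.with_correlation(
            var_intercept=10, var_slope=1, intercept_slope_correlation=0.4,
            var_residual=20,
        )
        s = precision_summary(d, p)
        assert s.ecr == pytest.approx(
            p.var_slope / (p.var_slope + s.effective_error), rel=1e-9
        )


designs = st.lists(
    st.floats(-5, 10), min_size=3, max_size=6, unique=True
).map(sorted).filter(lambda ts: all(b - a > 0.05 for a, b in zip(ts, ts[1:])))


class TestEffectiveErrorProperties:
    @settings(derandomize=True, max_examples=40)
    @given(times=designs, var_i=st.floats(0.1, 100), var_e=st.floats(0.5, 100))
    def test_monotone_in_variances_and_under_prolongation(self, times, var_i, var_e):
        d = StudyDesign(times)
        base = effective_error(d, var_i, var_e)
        assert effective_error(d, var_i, var_e * 1.5) >= base
        assert effective_error(d, var_i * 1.5, var_e) >= base
        # spreading occasions out (factor > 1) cannot hurt precision
        assert effective_error(scale_design(d, 2.0), var_i, var_e) <= base
        # adding an occasion cannot hurt precision
        extended = StudyDesign(list(times) + [max(times) + 1.0])
        assert effective_error(extended, var_i, var_e) <= base

    @settings(derandomize=True, max_examples=40)
    @given(times=designs, var_i=st.floats(0.1, 100), var_e=st.floats(0.5, 100))
    def test_sign_flip_symmetry(self, times, var_i, var_e):
        d = StudyDesign(times)
        flipped = StudyDesign(sorted(-t for t in times))
        assert effective_error(d, var_i, var_e) == pytest.approx(
            effective_error(flipped, var_i, var_e), rel=1e-12
        )

    @settings(derandomize=True, max_examples=40)
    @given(times=designs, var_i=st.floats(0.1, 100), var_e=st.floats(0.5, 100),
           delta=st.floats(-10, 10))
    def test_centered_design_is_the_pessimum_over_shifts(self, times, var_i, var_e,
                                                         delta):
        d = StudyDesign(times)
        centered = effective_error(center_design(d), var_i, var_e)
        shifted = effective_error(shift_design(center_design(d), delta), var_i, var_e)
        assert shifted <= centered * (1 + 1e-12)

    def test_limiting_equalities_with_grr(self):
        var_s, var_e = 1.0, 50.0
        d = StudyDesign([0, 1, 2, 3, 4])
        # centered design: ECR == GRR for any intercept variance
        c = center_design(d)
        for var_i in (0.0, 10.0, 500.0):
            eff = effective_error(c, var_i, var_e) if var_e > 0 else None
            assert ecr(var_s, eff) == pytest.approx(grr(var_s, var_e, c.sst), rel=1e-12)
        # ICC2 -> 1 (residual variance negligible relative to intercept variance)
        eff = effective_error(d, 1e12, var_e)
        assert ecr(var_s, eff) == pytest.approx(grr(var_s, var_e, d.sst), rel=1e-6)
        # var_i = 0 on a non-centered design: ECR uses sum t^2, NOT SST
        eff0 = effective_error(d, 0.0, var_e)
        assert eff0 == pytest.approx(var_e / 30)
        assert ecr(var_s, eff0) != pytest.approx(grr(var_s, var_e, d.sst), rel=1e-3)


class TestGeneralizedECR:
    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(times=designs, var_i=st.floats(1, 50), var_s=st.floats(0.05, 5),
           var_e=st.floats(1, 50))
    def test_matches_closed_form_when_covariance_is_zero(self, times, var_i, var_s,
                                                         var_e):
        d = StudyDesign(times)
        p = GrowthParams(var_intercept=var_i, var_slope=var_s, var_residual=var_e)
        closed = ecr(var_s, effective_error(d, var_i, var_e))
        computed = generalized_ecr(d, p, test="specific_1df",
                                   nuisance_policy="fixed_true")
        assert computed == pytest.approx(closed, abs=1e-6)

    def test_zero_slope_variance_gives_zero(self, annual_design):
        p = GrowthParams(var_intercept=10, var_slope=0, var_residual=50)
        assert generalized_ecr(annual_design, p, test="specific_1df") == 0.0

    def test_two_df_ecr_nondecreasing_in_correlation_magnitude(self, annual_design):
        values = []
        for rho in (0.0, 0.25, 0.5, 0.75):
            p = GrowthParams.with_correlation(
                var_intercept=10, var_slope=1, intercept_slope_correlation=rho,
                var_residual=50,
            )
            values.append(generalized_ecr(annual_design, p, test="generalized_2df"))
        assert all(b >= a - 1e-10 for a, b in zip(values, values[1:]))
        # and symmetric in the sign of the correlation? not exactly -- but
        # magnitude ordering must hold for negative correlations too
        p_neg = GrowthParams.with_correlation(
            var_intercept=10, var_slope=1, intercept_slope_correlation=-0.75,
            var_residual=50,
        )
        assert generalized_ecr(annual_design, p_neg, test="generalized_2df") \
            >= values[0] - 1e-10
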