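"""Tests for the four-step prediction workflow and its guard rails."""

import numpy as np
import pytest
from scipy.integrate import quad

from warfinr import (
    DomainError,
    DoseContext,
    InversionError,
    LogisticSlope,
    PairedSample,
    QuadraticMap,
    ValidityError,
    dose_for_target_inr,
    integral_slope,
    invert_dref,
    logistic_slope_at,
    predict,
    slope_from_pair,
    steady_state_inr,
    time_to_steady_state,
)
from warfinr.predict import _model_slope


def sample_from_si(t, si, vii=50.0, params=None):
    """Construct a paired sample whose approx_si equals the given SI."""
    from warfinr import PUBLISHED

    p = params or PUBLISHED
    return PairedSample(t=t, inr=si * vii / p.q, vii=vii)


class TestSlopeFromPair:
    def test_finite_difference(self, params):
        s1 = sample_from_si(3.0, 0.010)
        s2 = sample_from_si(4.0, 0.015)
        assert slope_from_pair(s1, s2, params) == pytest.approx(0.005, rel=1e-12)

    def test_identical_samples_give_zero_slope(self, params):
        s1 = sample_from_si(3.0, 0.010)
        s2 = sample_from_si(4.0, 0.010)
        assert slope_from_pair(s1, s2, params) == 0.0
        with pytest.raises(InversionError):
            invert_dref(0.0, 3.0, 4.0, params)

    def test_pre_equilibration_sample_rejected(self, params):
        s1 = sample_from_si(1.0, 0.010)
        s2 = sample_from_si(4.0, 0.015)
        with pytest.raises(ValidityError):
            slope_from_pair(s1, s2, params)

    def test_sample_ordering_enforced(self, params):
        s1 = sample_from_si(4.0, 0.010)
        s2 = sample_from_si(3.0, 0.015)
        with pytest.raises(DomainError):
            slope_from_pair(s1, s2, params)


class TestInvertDref:
    @pytest.mark.parametrize("dref", [6.0, 13.0, 1.0, 3.97])
    def test_forward_then_invert_round_trip(self, dref, params):
        model = LogisticSlope.from_dref(dref, params)
        slope = integral_slope(3.0, 4.0, model) / 1.0
        recovered = invert_dref(slope, 3.0, 4.0, params)
        assert recovered == pytest.approx(dref, rel=1e-6)

    def test_midpoint_mode_round_trip(self, params):
        model = LogisticSlope.from_dref(6.0, params)
        slope = logistic_slope_at(3.5, model)
        recovered = invert_dref(slope, 3.0, 4.0, params, mode="midpoint")
        assert recovered == pytest.approx(6.0, rel=1e-6)

    def test_nonpositive_slope_rejected(self, params):
        with pytest.raises(InversionError):
            invert_dref(0.0, 3.0, 4.0, params)
        with pytest.raises(InversionError):
            invert_dref(-1e-4, 3.0, 4.0, params)

    def test_slope_above_model_range_rejected(self, params):
        with pytest.raises(InversionError):
            invert_dref(1.0, 3.0, 4.0, params)  # far above any model slope

    def test_model_slope_monotone_on_bracket(self, params):
        # the bracketed root search relies on strict monotonicity in dose
        drefs = np.geomspace(0.01, 50.0, 200)
        vals = [_model_slope(d, 3.0, 4.0, params, "interval-mean") for d in drefs]
        assert np.all(np.diff(vals) > 0)


class TestTimeToSteadyState:
    @pytest.mark.parametrize(
        "dref,printed", [(3.97, 15.6), (9.90, 22.3)]
    )
    def test_published_typical_patient_values(self, dref, printed, params):
        assert time_to_steady_state(dref, params) == pytest.approx(printed, abs=0.1)

    @pytest.mark.parametrize("dref", [1.0, 2.5, 4.0, 7.0, 10.0, 13.0])
    def test_agrees_with_grid_scan_oracle(self, dref, params):
        # brute-force: first time on a 0.001-day grid where the slope is
        # at or below tolerance
        model = LogisticSlope.from_dref(dref, params)
        grid = np.arange(0.0, 60.0, 0.001)
        below = logistic_slope_at(grid, model) <= params.eps_si
        oracle = grid[np.argmax(below)]
        assert time_to_steady_state(dref, params) == pytest.approx(oracle, abs=0.001)

    def test_clamped_to_zero_when_tolerance_met_at_start(self, params):
        model = LogisticSlope.from_dref(1.0, params)
        loose = params.replace(eps_si=model.h / (1 + np.exp(-params.p * model.g)) * 1.01)
        assert time_to_steady_state(1.0, loose) == 0.0

    def test_nonpositive_dose_rejected(self, params):
        with pytest.raises(DomainError):
            time_to_steady_state(0.0, params)


class TestSteadyStateINR:
    @pytest.mark.parametrize(
        "dref,printed,tol", [(3.97, 2.28, 0.03), (13.3, 4.66, 0.03)]
    )
    def test_published_typical_patient_values(self, dref, printed, tol, params):
        assert steady_state_inr(dref, 1.0, params) == pytest.approx(printed, abs=tol)

    def test_additive_in_baseline_inr(self, params):
        a = steady_state_inr(5.0, 1.0, params)
        b = steady_state_inr(5.0, 1.5, params)
        assert b - a == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("dref", [1.0, 4.0, 7.0, 10.0, 13.0])
    def test_agrees_with_quadrature_oracle(self, dref, params):
        model = LogisticSlope.from_dref(dref, params)
        qm = QuadraticMap.from_dref(dref, params)
        t_ss = time_to_steady_state(dref, params)
        integrand = lambda t: qm.k * logistic_slope_at(t, model) ** 2 + qm.m * logistic_slope_at(t, model)
        oracle, _ = quad(integrand, 0.0, t_ss, epsabs=1e-12, epsrel=1e-12, limit=200)
        assert steady_state_inr(dref, 1.0, params) == pytest.approx(1.0 + oracle, rel=1e-8)

    def test_anticoagulation_never_lowers_inr(self, params):
        for dref in np.arange(1.0, 13.01, 0.5):
            assert steady_state_inr(dref, 1.0, params) >= 1.0


class TestPredictWorkflow:
    @pytest.mark.parametrize(
        "dref,t_exp,inr_exp",
        [(6.10, 18.7, 2.9), (7.32, 20.0, 3.2)],  # patients A and B
    )
    def test_real_patient_dref_reproduces_published_predictions(
        self, dref, t_exp, inr_exp, params
    ):
        # samples constructed so the inversion yields the published D_ref
        model = LogisticSlope.from_dref(dref, params)
        si1 = 0.01
        si2 = si1 + integral_slope(3.0, 4.0, model)
        s1, s2 = sample_from_si(3.0, si1), sample_from_si(4.0, si2)
        result = predict(s1, s2, DoseContext(dose=5.0), params)
        assert result.dref == pytest.approx(dref, rel=1e-6)
        assert result.t_ss_inr == pytest.approx(t_exp, abs=0.1)
        assert result.inr_ss == pytest.approx(inr_exp, abs=0.06)
        assert result.sensitivity_ratio == pytest.approx(dref / 5.0, rel=1e-6)

    def test_early_samples_rejected(self, params):
        s1 = sample_from_si(1.0, 0.010)
        s2 = sample_from_si(2.0, 0.015)
        with pytest.raises(ValidityError):
            predict(s1, s2, DoseContext(dose=5.0), params)

    def test_extrapolation_warnings(self, params):
        # a reference dose below the calibrated 1-13 mg/day range is flagged
        model = LogisticSlope.from_dref(0.5, params)
        si1 = 0.01
        si2 = si1 + integral_slope(3.0, 4.0, model)
        result = predict(
            sample_from_si(3.0, si1), sample_from_si(4.0, si2),
            DoseContext(dose=5.0), params,
        )
        assert any("dref_extrapolation" in w for w in result.warnings)
        # a reference dose above the range predicts INR above 4.7: both flags
        model = LogisticSlope.from_dref(14.5, params)
        si2 = si1 + integral_slope(3.0, 4.0, model)
        result = predict(
            sample_from_si(3.0, si1), sample_from_si(4.0, si2),
            DoseContext(dose=5.0), params,
        )
        assert any("dref_extrapolation" in w for w in result.warnings)
        assert any("inr_extrapolation" in w for w in result.warnings)

    def test_in_range_prediction_has_no_warnings(self, params):
        model = LogisticSlope.from_dref(6.0, params)
        si1 = 0.01
        si2 = si1 + integral_slope(3.0, 4.0, model)
        result = predict(
            sample_from_si(3.0, si1), sample_from_si(4.0, si2),
            DoseContext(dose=6.0), params,
        )
        assert result.warnings == ()

    def test_monotone_in_reference_dose(self, params):
        drefs = np.arange(1.0, 13.01, 0.25)
        t_ss = [time_to_steady_state(d, params) for d in drefs]
        inr = [steady_state_inr(d, 1.0, params) for d in drefs]
        assert np.all(np.diff(t_ss) > 0)
        assert np.all(np.diff(inr) > 0)


class TestDoseForTargetINR:
    def test_forward_inverse_round_trip(self, params):
        target = steady_state_inr(4.0, 1.0, params)
        assert dose_for_target_inr(target, 1.0, 1.0, params) == pytest.approx(4.0, rel=1e-9)

    def test_sensitivity_ratio_scaling(self, params):
        target = steady_state_inr(8.0, 1.0, params)
        assert dose_for_target_inr(target, 2.0, 1.0, params) == pytest.approx(4.0, rel=1e-9)

    def test_agrees_with_bisection_oracle(self, params, rng):
        def bisect(target, ratio, inr0):
            lo, hi = (b / ratio for b in params.dref_support)
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if steady_state_inr(ratio * mid, inr0, params) < target:
                    lo = mid
                else:
                    hi = mid
            return 0.5 * (lo + hi)

        for _ in range(20):
            ratio = rng.uniform(0.5, 2.0)
            dref = rng.uniform(1.5, 12.5)
            target = steady_state_inr(dref, 1.0, params)
            got = dose_for_target_inr(target, ratio, 1.0, params)
            assert got == pytest.approx(bisect(target, ratio, 1.0), abs=1e-6)

    def test_monotone_in_target(self, params):
        doses = [dose_for_target_inr(t, 1.0, 1.0, params) for t in (2.0, 2.5, 3.0, 3.5)]
        assert np.all(np.diff(doses) > 0)

    def test_unreachable_target_rejected(self, params):
        with pytest.raises(InversionError):
            dose_for_target_inr(8.0, 1.0, 1.0, params)
        with pytest.raises(DomainError):
            dose_for_target_inr(0.9, 1.0, 1.0, params)
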