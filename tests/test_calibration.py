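"""Dual-exponential dose-response fitting, evaluation and inversion."""

import json

import numpy as np
import pytest
import sympy

from filmdose import (CalibrationError, CalibrationModel, CalibrationPoint,
                      DomainError, DoseResponseModel, EBT_RED_COEFFICIENTS,
                      RangeError, ebt_reference_model, eval_dose,
                      fit_calibration, invert_dose)

A, B, C, D = EBT_RED_COEFFICIENTS


def sympy_dose(x, digits=30):
    """Independent high-precision evaluation of the reference curve."""
    xs = sympy.Rational(str(x))
    expr = (sympy.Rational("0.7424") * sympy.exp(sympy.Rational("3.094") * xs)
            + sympy.Rational("-0.8355")
            * sympy.exp(sympy.Rational("-4.848") * xs))
    return float(expr.evalf(digits))


class TestForwardEvaluation:
    def test_zero_nod_gives_negative_offset(self, ebt_model):
        # the curve does not pass through the origin
        assert ebt_model.dose(0.0, warn_extrapolation=False) == \
            pytest.approx(-0.0931, abs=1e-12)

    @pytest.mark.parametrize("x", [0.1, 0.30103, 0.5, 0.9, 1.2])
    def test_matches_high_precision_oracle(self, ebt_model, x):
        assert ebt_model.dose(x) == pytest.approx(sympy_dose(x), rel=1e-12)

    def test_log10_two_nod_is_about_1p69(self, ebt_model):
        assert ebt_model.dose(0.30103) == pytest.approx(1.690, abs=1e-3)

    def test_map_evaluation_broadcasts_scalar(self, ebt_model):
        m = np.full((4, 5), 0.5)
        np.testing.assert_allclose(ebt_model.dose(m), ebt_model.dose(0.5))

    def test_non_finite_rejected(self, ebt_model):
        with pytest.raises(DomainError):
            ebt_model.dose(np.array([0.5, np.nan]))

    def test_extrapolation_warns(self, ebt_model):
        with pytest.warns(UserWarning, match="outside calibrated"):
            ebt_model.dose(1.5)

    def test_strictly_increasing_on_range(self, ebt_model):
        grid = np.linspace(*ebt_model.nod_range, 1000)
        assert np.all(np.diff(ebt_model.dose(grid)) > 0)


class TestInversion:
    @pytest.mark.parametrize("x", [0.2, 0.5, 1.0])
    def test_round_trip_identity(self, ebt_model, x):
        assert ebt_model.invert(ebt_model.dose(x)) == pytest.approx(x, abs=1e-8)

    def test_known_dose(self, ebt_model):
        assert ebt_model.invert(1.6900797553020763) == \
            pytest.approx(0.30103, abs=1e-8)

    def test_dose_above_range_reports_achievable(self, ebt_model):
        with pytest.raises(RangeError) as err:
            ebt_model.invert(100.0)
        assert err.value.dose_max == pytest.approx(30.412423, abs=1e-4)

    def test_clip_mode(self, ebt_model):
        lo, hi = ebt_model.nod_range
        assert ebt_model.invert(100.0, out_of_range="clip") == pytest.approx(hi)
        assert ebt_model.invert(0.0, out_of_range="clip") == pytest.approx(lo)

    def test_array_inversion_hits_tolerance(self, ebt_model, rng):
        doses = rng.uniform(0.5, 30.0, (50,))
        x = ebt_model.invert(doses)
        np.testing.assert_allclose(ebt_model.dose(x), doses, atol=1e-9)


class TestFitting:
    def test_noiseless_self_consistency(self, ebt_model):
        xs = np.linspace(0.1, 1.2, 12)
        points = [CalibrationPoint(dose_gy=ebt_model.dose(x), nod=x)
                  for x in xs]
        fitted = fit_calibration(points)
        grid = np.linspace(0.1, 1.2, 300)
        rel = np.abs(fitted.dose(grid) - ebt_model.dose(grid)) \
            / ebt_model.dose(grid)
        assert rel.max() < 1e-4
        assert fitted.r_squared >= 0.999999

    def test_noisy_fit_recovers_curve(self, ebt_model):
        rng = np.random.default_rng(42)
        xs = np.linspace(0.1, 1.2, 12)
        doses = ebt_model.dose(xs) + rng.normal(0.0, 0.05, xs.size)
        fitted = DoseResponseModel(doses, xs).fit()
        assert fitted.r_squared >= 0.999
        grid = np.linspace(0.2, 1.2, 200)
        rel = np.abs(fitted.dose(grid) - ebt_model.dose(grid)) \
            / ebt_model.dose(grid)
        assert rel.max() < 0.02

    def test_refit_idempotence(self, ebt_model):
        xs = np.linspace(0.1, 1.2, 12)
        first = fit_calibration(
            [CalibrationPoint(ebt_model.dose(x), x) for x in xs])
        second = fit_calibration(
            [CalibrationPoint(first.dose(x), x) for x in xs])
        grid = np.linspace(0.1, 1.2, 100)
        rel = np.abs(second.dose(grid) - first.dose(grid)) / first.dose(grid)
        assert rel.max() < 1e-6

    def test_too_few_points_rejected(self, ebt_model):
        points = [CalibrationPoint(ebt_model.dose(x), x)
                  for x in (0.2, 0.5, 0.9)]
        with pytest.raises(DomainError, match="at least 5"):
            fit_calibration(points)

    def test_zero_nod_span_rejected(self):
        with pytest.raises(DomainError, match="zero NOD range"):
            DoseResponseModel([1, 2, 3, 4, 5], [0.5] * 5)

    def test_dataframe_constructor(self, ebt_model):
        import pandas as pd

        xs = np.linspace(0.1, 1.2, 8)
        df = pd.DataFrame({"dose_gy": ebt_model.dose(xs), "nod": xs})
        fitted = DoseResponseModel.from_dataframe(df).fit()
        assert fitted.n_points == 8

    def test_module_level_aliases(self, ebt_model):
        assert eval_dose(ebt_model, 0.5) == ebt_model.dose(0.5)
        assert invert_dose(ebt_model, 5.0) == ebt_model.invert(5.0)


class TestModelValidity:
    def test_non_monotone_curve_rejected(self):
        # growing negative exponential dominates: derivative < 0
        with pytest.raises(CalibrationError, match="increasing"):
            CalibrationModel.from_coefficients(
                0.01, 0.1, -2.0, 3.0, nod_range=(0.1, 1.2))

    def test_summary_mentions_fit_quality(self, ebt_model):
        xs = np.linspace(0.1, 1.2, 12)
        fitted = fit_calibration(
            [CalibrationPoint(ebt_model.dose(x), x) for x in xs])
        text = fitted.summary()
        assert "R-squared" in text and "NOD range" in text

    def test_json_round_trip(self, tmp_path, ebt_model):
        xs = np.linspace(0.1, 1.2, 12)
        fitted = fit_calibration(
            [CalibrationPoint(ebt_model.dose(x), x) for x in xs])
        path = tmp_path / "model.json"
        fitted.to_json(path)
        back = CalibrationModel.from_json(path)
        np.testing.assert_allclose(back.params, fitted.params)
        assert back.nod_range == fitted.nod_range
        assert back.r_squared == pytest.approx(fitted.r_squared)

    def test_reference_coefficients(self):
        model = ebt_reference_model()
        assert tuple(model.params) == (A, B, C, D)
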