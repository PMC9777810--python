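"""Prediction of a, hydrolysis-curve bands, and validation scoring."""

import warnings

import numpy as np
import pytest

from hydrokin import (
    fit_polynomial,
    fixed_b,
    percent_error,
    predict_a,
    predict_curve,
    validation_correlation,
)
from hydrokin.datasets import (
    default_assay,
    load_kinetic_constants,
    load_validation,
    reduced_model_terms,
    study_design,
)
from hydrokin.exceptions import ExtrapolationWarning, InputDataError
from hydrokin.prediction import PredictionResult


@pytest.fixture(scope="module")
def surfaces():
    """Reduced a- and b-surfaces refit from the bundled study constants."""
    x = study_design().coded
    out = {}
    for protease in ("alcalase", "protamex"):
        tab = load_kinetic_constants(protease)
        out[protease] = {
            "a": fit_polynomial(x, tab["a"], reduced_model_terms(protease, "a")),
            "b_fixed": fixed_b(
                fit_polynomial(x, tab["b"], reduced_model_terms(protease, "b"))
            ),
        }
    return out


class TestPredictA:
    def test_published_validation_predictions(self, surfaces):
        """Predicted a at every published validation condition within 1%."""
        for protease in ("alcalase", "protamex"):
            val = load_validation(protease)
            for _, row in val.iterrows():
                pred = predict_a(surfaces[protease]["a"], (row["x1"], row["x2"]))
                assert pred.value == pytest.approx(row["a_pred"], rel=0.01), (
                    protease,
                    (row["x1"], row["x2"]),
                )

    def test_center_prediction_is_intercept_without_quadratics(self, surfaces):
        res = surfaces["alcalase"]["a"]
        pred = predict_a(res, (0.0, 0.0))
        assert pred.value == pytest.approx(res.params["1"], rel=1e-12)

    def test_hat_matrix_identity_at_design_points(self, design_points, rng):
        """Full-model predictions at the design points equal the OLS fitted values."""
        y = rng.normal(10.0, 3.0, 10)
        res = fit_polynomial(design_points, y)
        for i in range(10):
            assert res.value_at(design_points[i]) == pytest.approx(
                res.fittedvalues[i], abs=1e-10
            )

    def test_band_nesting_with_confidence(self, surfaces):
        res = surfaces["alcalase"]["a"]
        lo = predict_a(res, (0.5, 0.5), confidence=0.90)
        hi = predict_a(res, (0.5, 0.5), confidence=0.99)
        assert hi.ci_low <= lo.ci_low <= lo.ci_high <= hi.ci_high

    def test_se_minimal_at_design_center(self, surfaces):
        res = surfaces["alcalase"]["a"]
        center_se = predict_a(res, (0.0, 0.0)).se
        grid = np.linspace(-1.0, 1.0, 9)
        for x1 in grid:
            for x2 in grid:
                assert predict_a(res, (x1, x2)).se >= center_se - 1e-12

    def test_extrapolation_warns(self, surfaces):
        with pytest.warns(ExtrapolationWarning):
            predict_a(surfaces["alcalase"]["a"], (2.0, 0.0))

    def test_paper_df_convention_widens_se(self, surfaces):
        res = surfaces["alcalase"]["a"]
        std = predict_a(res, (-0.5, 0.0), convention="standard")
        pap = predict_a(res, (-0.5, 0.0), convention="paper")
        assert pap.se > std.se
        # printed +/- for this condition was computed with the paper df
        assert pap.se == pytest.approx(0.44, abs=0.02)


class TestPredictCurve:
    def test_published_dh_after_60_min(self, surfaces):
        """Predicted DH at 60 min matches the published values within 1.5%."""
        assay = default_assay()
        times = np.linspace(0.0, 60.0, 61)
        for protease in ("alcalase", "protamex"):
            val = load_validation(protease)
            for _, row in val.iterrows():
                pred = predict_a(surfaces[protease]["a"], (row["x1"], row["x2"]))
                curve = predict_curve(pred, surfaces[protease]["b_fixed"], times, assay)
                assert curve.dh_at(60.0) == pytest.approx(row["dh_pred"], rel=0.015), (
                    protease,
                    (row["x1"], row["x2"]),
                )

    def test_band_ordering_and_start_at_zero(self, surfaces):
        pred = predict_a(surfaces["protamex"]["a"], (0.0, 1.0))
        curve = predict_curve(pred, surfaces["protamex"]["b_fixed"], np.linspace(0, 60, 31))
        assert curve.p_low[0] == curve.p_mid[0] == curve.p_high[0] == 0.0
        assert np.all(curve.p_low <= curve.p_mid + 1e-12)
        assert np.all(curve.p_mid <= curve.p_high + 1e-12)

    def test_zero_width_interval_gives_zero_width_band(self):
        pred = PredictionResult(x0=(0, 0), value=5.0, se=0.0, ci_low=5.0, ci_high=5.0)
        curve = predict_curve(pred, 0.04, np.linspace(0, 60, 7))
        np.testing.assert_allclose(curve.p_low, curve.p_mid)
        np.testing.assert_allclose(curve.p_high, curve.p_mid)

    def test_negative_lower_limit_clamped_with_warning(self):
        pred = PredictionResult(x0=(0, 0), value=1.0, se=2.0, ci_low=-3.0, ci_high=5.0)
        with pytest.warns(UserWarning, match="clamped"):
            curve = predict_curve(pred, 0.04, np.linspace(0, 60, 7))
        assert np.all(curve.p_low == 0.0)

    def test_time_grid_must_start_at_zero(self):
        pred = PredictionResult(x0=(0, 0), value=5.0, se=0.1, ci_low=4.8, ci_high=5.2)
        with pytest.raises(InputDataError):
            predict_curve(pred, 0.04, np.linspace(1.0, 60.0, 10))


class TestValidationScoring:
    def test_percent_error_examples(self):
        assert percent_error(14.6, 13.8) == pytest.approx(5.8, abs=0.1)
        assert percent_error(4.81, 3.92) == pytest.approx(22.7, abs=0.1)
        assert percent_error(7.0, 7.0) == 0.0

    def test_percent_error_zero_reference(self):
        with pytest.raises(InputDataError):
            percent_error(1.0, 0.0)

    def test_correlation_identity_and_sign_blindness(self):
        assert validation_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert validation_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(1.0)

    def test_correlation_on_published_validation_runs(self):
        """Predicted vs experimental a across the published validation runs
        correlates strongly (the study reports R^2 around 0.95 on its pooled set)."""
        val = load_validation()
        r2 = validation_correlation(val["a_pred"], val["a_exp"])
        assert 0.85 < r2 <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(InputDataError):
            validation_correlation([1.0, 1.0], [1.0, 2.0])
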