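"""Calibration fitting, inversion, series construction, transmittance conversion."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmas import (
    CalibrationCurve,
    CalibrationModel,
    DilutionSeriesSpec,
    EstimatorCoefficients,
    InsufficientDataError,
    InvalidInputError,
    RangeFlag,
    absorbance_to_transmittance,
    estimate_concentration,
    fit_loglinear,
    fit_transmittance_reference,
    invert,
    make_dilution_series,
    rounded_estimator,
)
from cmas.calibration import CONCENTRATION_COL, TRANSMITTANCE_COL, VOLTAGE_COL
from cmas.display import format_concentration, round_sig


def _noiseless_points(curve, concentrations, response=VOLTAGE_COL):
    return pd.DataFrame(
        {
            CONCENTRATION_COL: concentrations,
            response: curve.slope_a * np.log10(concentrations) + curve.intercept_b,
        }
    )


def _ols_oracle(x, y):
    """Closed-form normal equations, independent of statsmodels."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    r2 = 1.0 - np.sum(resid**2) / np.sum((y - ym) ** 2)
    return slope, intercept, r2


def test_fit_matches_closed_form_ols_on_noisy_data(sperm_curve, sperm_series):
    rng = np.random.default_rng(7)
    conc = np.repeat(sperm_series.concentrations(), 4)
    volts = sperm_curve.slope_a * np.log10(conc) + sperm_curve.intercept_b
    volts = volts + rng.normal(0, 0.05, volts.size)
    df = pd.DataFrame({CONCENTRATION_COL: conc, VOLTAGE_COL: volts})
    fit = fit_loglinear(df, c_min=1e8)
    mask = conc >= 1e8
    slope, intercept, r2 = _ols_oracle(np.log10(conc[mask]), volts[mask])
    assert fit.slope_a == pytest.approx(slope, rel=1e-10)
    assert fit.intercept_b == pytest.approx(intercept, rel=1e-10)
    assert fit.rsquared == pytest.approx(r2, rel=1e-10)


def test_noiseless_fit_recovers_generating_coefficients(sperm_curve, sperm_series):
    df = _noiseless_points(sperm_curve, sperm_series.concentrations())
    fit = fit_loglinear(df, c_min=1e8)
    assert fit.slope_a == pytest.approx(sperm_curve.slope_a, rel=1e-9)
    assert fit.intercept_b == pytest.approx(sperm_curve.intercept_b, rel=1e-9)
    assert fit.rsquared == pytest.approx(1.0, abs=1e-9)
    assert fit.c_max == sperm_series.start_concentration


def test_two_points_give_exact_line():
    df = pd.DataFrame({CONCENTRATION_COL: [1e8, 1e10], VOLTAGE_COL: [4.0, 0.0]})
    fit = fit_loglinear(df, c_min=1.0)
    assert fit.slope_a == pytest.approx(-2.0)
    assert fit.intercept_b == pytest.approx(20.0)
    assert fit.rsquared == pytest.approx(1.0)


def test_fewer_than_two_distinct_concentrations_rejected():
    df = pd.DataFrame({CONCENTRATION_COL: [1e9, 1e9, 5e7], VOLTAGE_COL: [2.0, 2.1, 3.9]})
    with pytest.raises(InsufficientDataError):
        fit_loglinear(df, c_min=1e8)


def test_range_restriction_improves_r2_on_plateau_data(sperm_curve, sperm_series):
    """Plateau points below c_min flatten the response and depress r²."""
    conc = sperm_series.concentrations()
    volts = [
        sperm_curve.slope_a * np.log10(max(c, sperm_curve.c_min)) + sperm_curve.intercept_b
        for c in conc
    ]
    rng = np.random.default_rng(3)
    volts = np.asarray(volts) + rng.normal(0, 0.01, len(volts))
    df = pd.DataFrame({CONCENTRATION_COL: conc, VOLTAGE_COL: volts})
    restricted = fit_loglinear(df, c_min=1e8)
    unrestricted = fit_loglinear(df, c_min=1.0)
    assert restricted.rsquared >= unrestricted.rsquared
    assert restricted.n_excluded == 4


@pytest.mark.parametrize(
    "slope, intercept, inv_slope, inv_intercept",
    [
        (-1.9658, 19.702, 0.5086987, 10.0223827),
        (-2.9698, 20.94, 0.3367230, 7.0509799),
        (-1.0, 0.0, 1.0, 0.0),
    ],
)
def test_exact_inversion(slope, intercept, inv_slope, inv_intercept):
    curve = CalibrationCurve(slope, intercept, 1e5, 1e10)
    est = invert(curve)
    assert est.inv_slope == pytest.approx(inv_slope, abs=1e-7)
    assert est.inv_intercept == pytest.approx(inv_intercept, abs=1e-7)


def test_rounded_estimator_reproduces_deployed_firmware_coefficients(sperm_curve, algae_curve):
    sperm = rounded_estimator(sperm_curve)
    assert (sperm.inv_slope, sperm.inv_intercept) == (0.508, 10.0)
    algae = rounded_estimator(algae_curve)
    assert (algae.inv_slope, algae.inv_intercept) == (0.337, 7.05)


def test_positive_slope_curve_is_rejected():
    with pytest.raises(InvalidInputError):
        CalibrationCurve(slope_a=1.0, intercept_b=0.0, c_min=1.0, c_max=10.0)


def test_estimate_round_trips_through_forward_model(sperm_curve):
    est = invert(sperm_curve)
    c, flag = estimate_concentration(est, 2.0098, sperm_curve)
    assert c == pytest.approx(1e9, rel=1e-4)
    assert flag is RangeFlag.IN_RANGE


def test_estimate_at_intercept_voltage_is_one_cell_and_below_range(sperm_curve):
    est = invert(sperm_curve)
    c, flag = estimate_concentration(est, sperm_curve.intercept_b, sperm_curve)
    assert c == pytest.approx(1.0, rel=1e-9)
    assert flag is RangeFlag.BELOW_RANGE


def test_estimate_flags_above_range(algae_curve):
    est = invert(algae_curve)
    v_low = algae_curve.slope_a * np.log10(algae_curve.c_max * 10) + algae_curve.intercept_b
    _, flag = estimate_concentration(est, v_low, algae_curve)
    assert flag is RangeFlag.ABOVE_RANGE


@settings(max_examples=50, deadline=None)
@given(
    slope=st.floats(min_value=-5.0, max_value=-0.2),
    intercept=st.floats(min_value=5.0, max_value=30.0),
    log_c=st.floats(min_value=5.5, max_value=9.5),
)
def test_roundtrip_identity_within_validity_range(slope, intercept, log_c):
    curve = CalibrationCurve(slope, intercept, c_min=1e5, c_max=1e10)
    v = slope * log_c + intercept
    c, _ = estimate_concentration(invert(curve), v, curve)
    assert c == pytest.approx(10.0**log_c, rel=1e-9)


def test_dilution_series_endpoints_and_ratios(sperm_series, algae_series):
    sperm = make_dilution_series(sperm_series)
    algae = make_dilution_series(algae_series)
    assert sperm[0] == 4.0e9 and len(sperm) == 10
    assert round_sig(sperm[-1]) == 7.8e6
    assert round_sig(algae[-1]) == 2.8e4
    assert format_concentration(sperm[-1]) == "7.8e+06"
    np.testing.assert_allclose(sperm[:-1] / sperm[1:], 2.0, rtol=1e-12)
    # geometric symmetry for ratio-2 series
    assert sperm[0] * sperm[-1] == pytest.approx(sperm[1] * sperm[-2], rel=1e-12)


def test_single_sample_series_is_just_the_start():
    series = DilutionSeriesSpec(1e6, 1)
    np.testing.assert_array_equal(make_dilution_series(series), [1e6])


@pytest.mark.parametrize("absorbance, pct_t", [(0.0, 100.0), (2.0, 1.0), (1.0, 10.0)])
def test_absorbance_to_transmittance_values(absorbance, pct_t):
    assert absorbance_to_transmittance(absorbance) == pytest.approx(pct_t, rel=1e-12)


@given(st.floats(min_value=-1.0, max_value=4.0), st.floats(min_value=0.01, max_value=1.0))
def test_transmittance_strictly_decreasing_in_absorbance(a, step):
    assert absorbance_to_transmittance(a + step) < absorbance_to_transmittance(a)


def test_transmittance_reference_fit_recovery(algae_series):
    ref = CalibrationCurve(-35.358, 298.92, 3e5, 3.6e6, label="%T reference")
    conc = algae_series.concentrations()
    df = pd.DataFrame(
        {
            CONCENTRATION_COL: conc,
            TRANSMITTANCE_COL: ref.slope_a * np.log10(conc) + ref.intercept_b,
        }
    )
    fit = fit_transmittance_reference(df, c_min=3e5)
    assert fit.slope_a == pytest.approx(-35.358, rel=1e-9)
    assert fit.intercept_b == pytest.approx(298.92, rel=1e-9)


def test_noisier_reference_fit_has_lower_r2_than_sensor_fit(algae_curve, algae_series):
    """Matched-noise comparison: the %T reference responds less linearly (in r² terms)
    when its residual scatter is proportionally larger."""
    rng = np.random.default_rng(11)
    conc = np.repeat(algae_series.concentrations(), 4)
    sensor = algae_curve.slope_a * np.log10(conc) + algae_curve.intercept_b
    sensor += rng.normal(0, 0.05, conc.size)
    ref_curve = CalibrationCurve(-35.358, 298.92, 3e5, 3.6e6)
    ref = ref_curve.slope_a * np.log10(conc) + ref_curve.intercept_b
    ref += rng.normal(0, 12.0, conc.size)  # SD scaled so r2 lands near 0.84
    fit_sensor = fit_loglinear(
        pd.DataFrame({CONCENTRATION_COL: conc, VOLTAGE_COL: sensor}), c_min=3e5
    )
    fit_ref = fit_transmittance_reference(
        pd.DataFrame({CONCENTRATION_COL: conc, TRANSMITTANCE_COL: ref}), c_min=3e5
    )
    assert fit_ref.rsquared < fit_sensor.rsquared


def test_csv_and_json_round_trips(tmp_path, sperm_curve, sperm_series):
    df = _noiseless_points(sperm_curve, sperm_series.concentrations())
    df["replicate"] = 1
    csv = tmp_path / "points.csv"
    df.to_csv(csv, index=False)
    fit = CalibrationModel.from_csv(csv, c_min=1e8, label="sperm").fit()
    assert fit.slope_a == pytest.approx(sperm_curve.slope_a, rel=1e-9)

    out = tmp_path / "curve.json"
    fit.curve.to_json(out)
    restored = CalibrationCurve(**json.loads(out.read_text()))
    assert restored.slope_a == fit.curve.slope_a
    assert restored.label == "sperm"


def test_summary_reports_fit_and_inverse(sperm_curve, sperm_series):
    df = _noiseless_points(sperm_curve, sperm_series.concentrations())
    text = fit_loglinear(df, c_min=1e8, label="sperm").summary()
    assert "slope" in text and "r-squared" in text and "inverse" in text and "sperm" in text


def test_estimator_coefficients_validate():
    with pytest.raises(InvalidInputError):
        EstimatorCoefficients(inv_intercept=10.0, inv_slope=-0.5)
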