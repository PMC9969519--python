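"""Digital-twin simulator: dataset generation, blind trial, auto-dilution, summaries."""

import numpy as np
import pytest

from cmas import (
    InvalidInputError,
    TwinConfig,
    fit_loglinear,
    generate_calibration_dataset,
    invert,
    run_blind_trial,
    simulate_auto_dilution,
    summarize_trial,
)
from cmas.calibration import CONCENTRATION_COL, VOLTAGE_COL


def test_dataset_has_one_point_per_concentration_per_pull(sperm_curve, sperm_series):
    df = generate_calibration_dataset(sperm_curve, sperm_series, 4, TwinConfig(rng_seed=0))
    assert len(df) == 40
    assert df["replicate"].nunique() == 4
    assert df[CONCENTRATION_COL].nunique() == 10


def test_noiseless_replicates_are_identical(sperm_curve, sperm_series, ideal_twin):
    df = generate_calibration_dataset(sperm_curve, sperm_series, 4, ideal_twin)
    assert (df.groupby(CONCENTRATION_COL)[VOLTAGE_COL].nunique() == 1).all()


def test_fixed_seed_gives_byte_identical_csv(sperm_curve, sperm_series, tmp_path):
    twin = TwinConfig(noise_sd=0.02, rng_seed=123)
    paths = []
    for name in ("a.csv", "b.csv"):
        p = tmp_path / name
        generate_calibration_dataset(sperm_curve, sperm_series, 4, twin).to_csv(p, index=False)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_recovered_slope_within_three_se_in_at_least_95pct_of_seeds(sperm_curve, sperm_series):
    hits = 0
    for seed in range(200):
        twin = TwinConfig(noise_sd=0.05, rng_seed=seed)
        df = generate_calibration_dataset(sperm_curve, sperm_series, 4, twin)
        fit = fit_loglinear(df, c_min=1e8)
        if abs(fit.slope_a - sperm_curve.slope_a) <= 3 * fit.slope_se:
            hits += 1
    assert hits >= 190


def test_blind_trial_noiseless_identity_above_validity_bound(sperm_curve, sperm_series, ideal_twin):
    df = run_blind_trial(sperm_curve, sperm_series, 2, ideal_twin, shuffle_seed=5)
    in_range = df[df["known"] >= sperm_curve.c_min]
    np.testing.assert_allclose(in_range["estimated"], in_range["known"], rtol=1e-9)


def test_blind_trial_flags_and_plateaus_below_range(sperm_curve, sperm_series, ideal_twin):
    """Sub-range samples read the plateau voltage and pile up at ~c_min."""
    df = run_blind_trial(sperm_curve, sperm_series, 1, ideal_twin, shuffle_seed=5)
    below = df[df["known"] < sperm_curve.c_min]
    assert (below["flag"] == "below_range").all()
    np.testing.assert_allclose(below["estimated"], sperm_curve.c_min, rtol=1e-9)


def test_blind_trial_shuffle_independent_of_noise_seed(sperm_curve, sperm_series):
    twin = TwinConfig(noise_sd=0.02, rng_seed=1)
    a = run_blind_trial(sperm_curve, sperm_series, 1, twin, shuffle_seed=7)
    b = run_blind_trial(sperm_curve, sperm_series, 1, twin, shuffle_seed=7)
    c = run_blind_trial(sperm_curve, sperm_series, 1, twin, shuffle_seed=8)
    assert a["known"].tolist() == b["known"].tolist()
    assert a["known"].tolist() != c["known"].tolist()


def test_noise_propagates_to_log10_estimate_sd(sperm_curve):
    """Monte Carlo error propagation: SD of log10(estimate) ~= noise_sd / |a|."""
    from cmas import OpticalConfig, estimate_concentration, sensor_voltage

    noise_sd = 0.02
    rng = np.random.default_rng(0)
    est = invert(sperm_curve)
    logs = []
    for _ in range(10_000):
        v = sensor_voltage(1e9, sperm_curve, noise_sd=noise_sd, rng=rng).voltage
        c, _ = estimate_concentration(est, v, sperm_curve)
        logs.append(np.log10(c))
    expected = noise_sd / abs(sperm_curve.slope_a)
    assert np.std(logs) == pytest.approx(expected, rel=0.05)


def test_auto_dilution_noiseless_lossless_hits_target(algae_curve, ideal_twin):
    result = simulate_auto_dilution(3.6e6, 1.0e6, 5, ideal_twin, algae_curve)
    np.testing.assert_allclose(result.final_concentrations, 1.0e6, rtol=1e-9)
    assert result.sd == pytest.approx(0.0, abs=1e-3)
    assert result.pct_of_target == pytest.approx(100.0, rel=1e-9)


def test_auto_dilution_loss_closed_form(algae_curve):
    twin = TwinConfig(noise_sd=0.0, loss_fraction=0.10, rng_seed=0)
    result = simulate_auto_dilution(3.6e6, 1.0e6, 5, twin, algae_curve)
    assert result.mean == pytest.approx(0.9e6, rel=1e-9)
    assert result.pct_of_target == pytest.approx(90.0, rel=1e-9)


def test_auto_dilution_with_pumps_quantizes_volumes(algae_curve, ideal_twin):
    from cmas import PumpConfig

    result = simulate_auto_dilution(
        3.6e6, 1.0e6, 3, ideal_twin, algae_curve,
        sample_pump=PumpConfig(pump_id="s"), diluent_pump=PumpConfig(pump_id="d"),
    )
    # step quantization keeps the outcome within half a step per pump of target
    assert result.mean == pytest.approx(1.0e6, rel=1e-3)


def test_auto_dilution_requires_dilutable_input(algae_curve, ideal_twin):
    with pytest.raises(InvalidInputError):
        simulate_auto_dilution(1.0e6, 2.0e6, 5, ideal_twin, algae_curve)


def test_auto_dilution_is_seed_deterministic(algae_curve):
    twin = TwinConfig(noise_sd=0.02, loss_fraction=0.15, rng_seed=11)
    a = simulate_auto_dilution(3.6e6, 1.0e6, 5, twin, algae_curve)
    b = simulate_auto_dilution(3.6e6, 1.0e6, 5, twin, algae_curve)
    assert a.final_concentrations == b.final_concentrations


def test_summarize_trial_hand_computed_statistics():
    result = summarize_trial([6e5, 8e5, 10e5], target=1e6)
    assert result.mean == pytest.approx(8e5)
    assert result.sd == pytest.approx(2e5)  # sample SD, n-1 denominator
    assert result.precision_pct == pytest.approx(25.0)
    assert result.pct_of_target == pytest.approx(80.0)


def test_summarize_trial_reference_accuracy():
    result = summarize_trial([8.9e5] * 5, target=1e6)
    assert result.pct_of_target == pytest.approx(89.0)
    assert result.sd == 0.0 and result.precision_pct == 0.0


def test_summarize_trial_rejects_empty_and_bad_target():
    with pytest.raises(InvalidInputError):
        summarize_trial([], 1e6)
    with pytest.raises(InvalidInputError):
        summarize_trial([1e6], 0.0)
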