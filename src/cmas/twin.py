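"""Digital-twin simulator and synthetic-data generator.

The twin replaces the physical instrument in tests and desk studies. It
emulates the reference experiments: serial 1:1 dilution series measured in
repeated "pulls" (catfish sperm from 4.0e9 cells/mL, *Tetraselmis chuii*
algae from 3.6e6 cells/mL), a single-blinded estimation trial on shuffled
samples, and closed-loop automatic dilution to a target concentration.

Two imperfections are modelled: additive Gaussian voltage noise on each
reading (default SD 0.02 V) and a single multiplicative cell-loss fraction
per pass (cells adhering to tubing walls, etc. — magnitude only, no claimed
mechanism). Everything is driven by seeded numpy Generators, so identical
configurations reproduce identical outputs.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import optics
from .calibration import (
    CONCENTRATION_COL,
    REPLICATE_COL,
    VOLTAGE_COL,
    CalibrationCurve,
    DilutionSeriesSpec,
    EstimatorCoefficients,
    RangeFlag,
    estimate_concentration,
    invert,
    make_dilution_series,
)
from .dilution import plan_dilution
from .errors import InvalidInputError
from .pumping import PumpConfig, schedule_ratio_flow

__all__ = [
    "TwinConfig",
    "TrialResult",
    "generate_calibration_dataset",
    "run_blind_trial",
    "simulate_auto_dilution",
    "summarize_trial",
]


@dataclass(frozen=True)
class TwinConfig:
    """Imperfection model of the simulated instrument.

    noise_sd : additive Gaussian voltage noise SD, volts (default 0.02 V).
    loss_fraction : fraction of cells lost to the fluid path per pass, in [0, 1).
    rng_seed : seed for measurement noise.
    adc_quantize : snap voltages to the 10-bit ADC grid.
    """

    noise_sd: float = 0.02
    loss_fraction: float = 0.0
    rng_seed: int = 0
    adc_quantize: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be nonnegative")
        if not 0 <= self.loss_fraction < 1:
            raise InvalidInputError("loss_fraction must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)

    def with_(self, **changes) -> "TwinConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class TrialResult:
    """Summary of repeated dilution trials against one target concentration."""

    final_concentrations: tuple[float, ...]
    target: float
    mean: float
    sd: float
    precision_pct: float  # coefficient of variation, sd/mean * 100
    pct_of_target: float  # accuracy, mean/target * 100

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "final_concentrations": list(self.final_concentrations),
                "target": self.target,
                "mean": self.mean,
                "sd": self.sd,
                "precision_pct": self.precision_pct,
                "pct_of_target": self.pct_of_target,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n", encoding="utf-8")
        return payload


def summarize_trial(final_concentrations: Sequence[float], target: float) -> TrialResult:
    """Mean, sample SD (n-1), CV% and accuracy (% of target) of trial outcomes."""
    values = [float(v) for v in final_concentrations]
    if not values:
        raise InvalidInputError("final_concentrations must be nonempty")
    if target <= 0:
        raise InvalidInputError("target must be positive")
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    return TrialResult(
        final_concentrations=tuple(values),
        target=float(target),
        mean=mean,
        sd=sd,
        precision_pct=sd / mean * 100.0,
        pct_of_target=mean / target * 100.0,
    )


def generate_calibration_dataset(
    curve: CalibrationCurve,
    series: DilutionSeriesSpec,
    n_pulls: int,
    twin: TwinConfig | None = None,
    config: optics.OpticalConfig | None = None,
) -> pd.DataFrame:
    """Simulate measuring a serial-dilution series in repeated pulls.

    One reading per concentration per pull, pulled from highest to lowest
    concentration within each pull (mirroring bench practice). Returns a
    DataFrame with the standard calibration-CSV columns; fixed seeds give
    byte-identical CSV output.
    """
    if n_pulls < 1:
        raise InvalidInputError("n_pulls must be >= 1")
    tw = twin or TwinConfig()
    cfg = (config or optics.OpticalConfig()).with_(adc_quantize=tw.adc_quantize)
    rng = tw.rng()
    concentrations = make_dilution_series(series)
    rows = []
    for pull in range(1, n_pulls + 1):
        for c in concentrations:
            reading = optics.sensor_voltage(c, curve, cfg, noise_sd=tw.noise_sd, rng=rng)
            rows.append({CONCENTRATION_COL: c, VOLTAGE_COL: reading.voltage, REPLICATE_COL: pull})
    return pd.DataFrame(rows, columns=[CONCENTRATION_COL, VOLTAGE_COL, REPLICATE_COL])


def run_blind_trial(
    curve: CalibrationCurve,
    series: DilutionSeriesSpec,
    n_replicates: int,
    twin: TwinConfig | None = None,
    shuffle_seed: int | None = None,
    estimator: EstimatorCoefficients | None = None,
    config: optics.OpticalConfig | None = None,
) -> pd.DataFrame:
    """Single-blinded estimation trial: measure shuffled samples, invert to concentrations.

    The shuffle uses its own seed, independent of the measurement-noise seed,
    so sample order and noise are separately reproducible. Samples whose
    known concentration lies below the curve's validity bound are flagged
    ``below_range``; their plateau voltage maps to approximately ``c_min``.

    Returns a DataFrame with columns ``known``, ``voltage_v``, ``estimated``
    and ``flag`` in measurement order.
    """
    if n_replicates < 1:
        raise InvalidInputError("n_replicates must be >= 1")
    tw = twin or TwinConfig()
    cfg = (config or optics.OpticalConfig()).with_(adc_quantize=tw.adc_quantize)
    est = estimator or invert(curve)
    samples = [
        (float(c), rep)
        for rep in range(1, n_replicates + 1)
        for c in make_dilution_series(series)
    ]
    order = np.random.default_rng(shuffle_seed).permutation(len(samples))
    rng = tw.rng()
    rows = []
    for idx in order:
        known, rep = samples[idx]
        reading = optics.sensor_voltage(known, curve, cfg, noise_sd=tw.noise_sd, rng=rng)
        estimated, flag = estimate_concentration(est, reading.voltage, curve)
        if known < curve.c_min:
            flag = RangeFlag.BELOW_RANGE
        rows.append(
            {
                "known": known,
                "replicate": rep,
                VOLTAGE_COL: reading.voltage,
                "estimated": estimated,
                "flag": flag.value,
            }
        )
    return pd.DataFrame(rows)


def simulate_auto_dilution(
    c_start: float,
    c_target: float,
    n_trials: int,
    twin: TwinConfig | None = None,
    curve: CalibrationCurve | None = None,
    sample_pump: PumpConfig | None = None,
    diluent_pump: PumpConfig | None = None,
    sample_volume_ml: float = 1.0,
    config: optics.OpticalConfig | None = None,
) -> TrialResult:
    """Closed-loop automatic dilution repeated over trials.

    Each trial measures the starting sample (noisy voltage -> inverse
    estimate), plans a dilution to the target from that estimate, executes it
    on the true concentration, and applies the loss fraction. When pump
    configs are supplied, delivered volumes are step-quantized through the
    flow scheduler; otherwise delivery is ideal (exact volumes), keeping the
    noiseless, lossless limit exact.
    """
    if curve is None:
        raise InvalidInputError("a calibration curve is required")
    if c_start <= c_target:
        raise InvalidInputError("c_start must exceed c_target for a dilution trial")
    if n_trials < 1:
        raise InvalidInputError("n_trials must be >= 1")
    tw = twin or TwinConfig()
    cfg = (config or optics.OpticalConfig()).with_(adc_quantize=tw.adc_quantize)
    est = invert(curve)
    rng = tw.rng()
    finals = []
    for _ in range(n_trials):
        reading = optics.sensor_voltage(c_start, curve, cfg, noise_sd=tw.noise_sd, rng=rng)
        c_measured, _flag = estimate_concentration(est, reading.voltage, curve)
        plan = plan_dilution(c_measured, c_target, sample_volume_ml)
        if sample_pump is not None or diluent_pump is not None:
            flow = schedule_ratio_flow(
                plan.sample_volume_ml, plan.flow_ratio, sample_pump, diluent_pump
            )
            v_sample, v_diluent = flow.sample.delivered_ml, flow.diluent.delivered_ml
        else:
            v_sample, v_diluent = plan.sample_volume_ml, plan.diluent_volume_ml
        # executed on the TRUE concentration; estimation error shifts the outcome
        cells_out = c_start * v_sample * (1.0 - tw.loss_fraction)
        finals.append(cells_out / (v_sample + v_diluent))
    return summarize_trial(finals, c_target)
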