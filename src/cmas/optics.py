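"""Forward model of the optical evaluation module (digital twin of the sensor).

The physical chain is: a 12-bit DAC drives an LED, light crosses 1 mm of
sample-filled tubing, a photodiode signal is amplified (gain 20) and read by a
10-bit ADC. The twin does not model the photophysics; it uses the empirical
log-linear voltage response of a fitted :class:`~cmas.calibration.CalibrationCurve`
as its forward model, with a plateau below the curve's lower validity bound
(dilute samples become indistinguishable) and a clamp above the upper bound
(voltages cannot extrapolate below zero). Additive Gaussian voltage noise and
optional ADC quantization complete the sensor model.

Only the red LED channel (peak 624 nm) is modelled; green and blue are
configuration placeholders.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping

import numpy as np

from .calibration import CalibrationCurve
from .errors import CalibrationFailureError, InvalidInputError

__all__ = [
    "DAC_CODES",
    "LedChannel",
    "OpticalConfig",
    "SensorReading",
    "SaturationStatus",
    "dac_resolution",
    "noiseless_voltage",
    "sensor_voltage",
    "quantize_adc",
    "baseline_calibrate",
    "saturation_check",
]

DAC_CODES = 4096  # 12-bit DAC: codes 0..4095


class LedChannel(enum.Enum):
    RED = 624
    GREEN = 525
    BLUE = 470

    @property
    def wavelength_nm(self) -> int:
        return self.value


class SaturationStatus(enum.Enum):
    OK = "ok"
    LOW_SATURATED = "low_saturated"
    HIGH_SATURATED = "high_saturated"


@dataclass(frozen=True)
class OpticalConfig:
    """Electronics and geometry of the optical evaluation module.

    Defaults mirror the reference build: 5 V supply, 12-bit DAC, op-amp gain
    20, 10-bit ADC, 1 mm optical path, 1.50 V empty-tube baseline, and a
    usable output window of roughly 0.5-4.1 V (opaque dye to deionized
    water). ``adc_quantize`` is off by default so analytic tests stay exact;
    ``n_adc_samples`` averages repeated ADC draws per reading.
    """

    led_channel: LedChannel = LedChannel.RED
    dac_code: int = 2048
    supply_voltage: float = 5.0
    amp_gain: float = 20.0
    adc_bits: int = 10
    baseline_target: float = 1.50
    path_length_mm: float = 1.0
    voltage_floor: float = 0.5
    voltage_ceiling: float = 4.1
    adc_quantize: bool = False
    n_adc_samples: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.dac_code < DAC_CODES:
            raise InvalidInputError(f"dac_code must be in [0, {DAC_CODES - 1}]")
        if not self.voltage_floor < self.baseline_target < self.voltage_ceiling < self.supply_voltage:
            raise InvalidInputError(
                "need voltage_floor < baseline_target < voltage_ceiling < supply_voltage"
            )
        if self.amp_gain <= 0:
            raise InvalidInputError("amp_gain must be positive")
        if self.n_adc_samples < 1:
            raise InvalidInputError("n_adc_samples must be >= 1")

    def with_(self, **changes) -> "OpticalConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class SensorReading:
    voltage: float
    timestamp_s: float
    channel: LedChannel
    in_range: bool


def dac_resolution(config: OpticalConfig | float | None = None) -> float:
    """DAC output step in volts per code: supply / 4095 (about 1.2 mV at 5 V).

    Accepts an :class:`OpticalConfig` or a bare supply voltage in volts.
    """
    if config is None:
        supply = OpticalConfig().supply_voltage
    elif isinstance(config, OpticalConfig):
        supply = config.supply_voltage
    else:
        supply = float(config)
    if supply < 0:
        raise InvalidInputError("supply_voltage must be nonnegative")
    return supply / (DAC_CODES - 1)


def quantize_adc(voltage: float, config: OpticalConfig) -> float:
    """Snap a voltage to the nearest ADC level (adc_bits over 0..supply)."""
    levels = 2**config.adc_bits - 1
    step = config.supply_voltage / levels
    return round(voltage / step) * step


def noiseless_voltage(
    concentration: float, curve: CalibrationCurve, config: OpticalConfig | None = None
) -> float:
    """Deterministic forward response: log-linear inside the validity range,
    plateau below c_min, clamp above c_max, clipped to [0, supply]."""
    cfg = config or OpticalConfig()
    if concentration <= 0:
        raise InvalidInputError("concentration must be positive")
    c_eff = min(max(concentration, curve.c_min), curve.c_max)
    v = curve.slope_a * math.log10(c_eff) + curve.intercept_b
    return min(max(v, 0.0), cfg.supply_voltage)


def sensor_voltage(
    concentration: float,
    curve: CalibrationCurve,
    config: OpticalConfig | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    timestamp_s: float = 0.0,
) -> SensorReading:
    """Simulate one sensor reading at a given cell concentration.

    Noise is additive Gaussian on voltage (SD ``noise_sd``); pass a seeded
    ``numpy`` Generator (or int seed) for reproducibility. When the config
    requests it, the voltage is averaged over ``n_adc_samples`` independent
    draws and quantized to the ADC grid.
    """
    cfg = config or OpticalConfig()
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be nonnegative")
    v = noiseless_voltage(concentration, curve, cfg)
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        draws = v + gen.normal(0.0, noise_sd, size=cfg.n_adc_samples)
        v = float(np.mean(draws))
    v = min(max(v, 0.0), cfg.supply_voltage)
    if cfg.adc_quantize:
        v = quantize_adc(v, cfg)
    return SensorReading(
        voltage=v,
        timestamp_s=timestamp_s,
        channel=cfg.led_channel,
        in_range=cfg.voltage_floor < v < cfg.voltage_ceiling,
    )


def saturation_check(reading: SensorReading, config: OpticalConfig | None = None) -> SaturationStatus:
    """Classify a reading against the usable output window."""
    cfg = config or OpticalConfig()
    if reading.voltage <= cfg.voltage_floor:
        return SaturationStatus.LOW_SATURATED
    if reading.voltage >= cfg.voltage_ceiling:
        return SaturationStatus.HIGH_SATURATED
    return SaturationStatus.OK


def baseline_calibrate(
    blank_response: Callable[[int], float] | Mapping[int, float],
    target: float = 1.50,
    tolerance: float = 0.002,
    n_codes: int = DAC_CODES,
) -> int:
    """Find the DAC code whose empty-tube ("blank") voltage best matches the target.

    ``blank_response`` maps DAC code to the amplified blank-tube voltage and
    must be monotone nondecreasing in code. The search bisects for the
    crossing and refines among neighbours, which for a monotone response is
    equivalent to the exhaustive argmin over all codes; ties between two
    equally close codes break toward the higher code. Raises
    :class:`CalibrationFailureError` if no code lands within ``tolerance``.
    """
    f = blank_response.__getitem__ if isinstance(blank_response, Mapping) else blank_response
    lo, hi = 0, n_codes - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if f(mid) < target:
            lo = mid + 1
        else:
            hi = mid
    best, best_d = None, math.inf
    for code in sorted({max(lo - 1, 0), lo, min(lo + 1, n_codes - 1)}):
        d = abs(f(code) - target)
        if d <= best_d + 1e-12:  # tie -> higher code
            best, best_d = code, min(best_d, d)
    if best_d > tolerance:
        raise CalibrationFailureError(
            f"no DAC code reaches {target} V within {tolerance} V (best miss {best_d:.4g} V)"
        )
    return best
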