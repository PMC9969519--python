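"""Peristaltic pump flow planning.

Each pump is a six-roller peristaltic head on a NEMA 17 stepper (200 full
steps/rev); delivered volume is proportional to step count through a
per-build calibration constant ``volume_per_step_ul``. The electronics limit
each pump to ``max_flow_ml_min`` (1.1 mL/min on the reference build). Flow is
treated as continuous and viscosity-independent over the working range
(water to 20% glycerol, ~0.96-1.68 cP); a ``viscosity_cp`` annotation on the
config is carried for documentation but never used in planning.

Dilution mixing happens at a T-junction where the sample pump and the
diluent pump run simultaneously at a flow-rate ratio equal to the planned
diluent:sample volume ratio; the faster requirement binds (one pump at its
maximum, the other scaled down). A sequential mode (``co_flow=False``) runs
each pump at its own maximum instead.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

from .errors import InvalidInputError

__all__ = [
    "PumpConfig",
    "PumpChannelPlan",
    "FlowPlan",
    "steps_for_volume",
    "max_rate_time",
    "schedule_ratio_flow",
]

_RATE_EPS = 1e-9


@dataclass(frozen=True)
class PumpConfig:
    """Stepper/tubing geometry of one pump.

    ``volume_per_step_ul`` is a per-build calibration constant (measure it by
    weighing delivered water); the 0.5 µL/step default gives the reference
    1.1 mL/min at a plausible 36.7 steps/s.
    """

    steps_per_rev: int = 200
    volume_per_step_ul: float = 0.5
    max_flow_ml_min: float = 1.1
    pump_id: str = "pump"
    viscosity_cp: float = 1.0  # annotation only; flow is viscosity-independent

    def __post_init__(self) -> None:
        if self.steps_per_rev <= 0 or self.volume_per_step_ul <= 0 or self.max_flow_ml_min <= 0:
            raise InvalidInputError("pump geometry and rate limit must be positive")


@dataclass(frozen=True)
class PumpChannelPlan:
    """One pump's share of a coordinated flow."""

    pump_id: str
    flow_rate_ml_min: float
    duration_s: float
    step_count: int
    volume_ml: float  # requested volume
    delivered_ml: float  # step-quantized volume actually delivered


@dataclass(frozen=True)
class FlowPlan:
    sample: PumpChannelPlan
    diluent: PumpChannelPlan
    ratio_requested: float
    co_flow: bool = True

    def __post_init__(self) -> None:
        for ch in (self.sample, self.diluent):
            if ch.step_count < 0 or ch.volume_ml < 0:
                raise InvalidInputError("negative step count or volume in flow plan")

    @property
    def ratio_achieved(self) -> float:
        """Delivered diluent:sample volume ratio after step quantization."""
        return self.diluent.delivered_ml / self.sample.delivered_ml if self.sample.delivered_ml else math.inf

    @property
    def total_delivered_ml(self) -> float:
        return self.sample.delivered_ml + self.diluent.delivered_ml

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "sample": asdict(self.sample),
                "diluent": asdict(self.diluent),
                "ratio_requested": self.ratio_requested,
                "ratio_achieved": self.ratio_achieved,
                "co_flow": self.co_flow,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n", encoding="utf-8")
        return payload


def steps_for_volume(volume_ml: float, config: PumpConfig) -> int:
    """Step count delivering a volume, rounded half-up to the nearest step.

    The delivered-volume error is at most half of ``volume_per_step_ul``.
    """
    if volume_ml < 0:
        raise InvalidInputError("volume must be nonnegative")
    return int(math.floor(volume_ml * 1000.0 / config.volume_per_step_ul + 0.5))


def delivered_volume_ml(steps: int, config: PumpConfig) -> float:
    return steps * config.volume_per_step_ul / 1000.0


def max_rate_time(volume_ml: float, config: PumpConfig) -> float:
    """Seconds to deliver a volume at the pump's maximum flow rate."""
    if volume_ml < 0:
        raise InvalidInputError("volume must be nonnegative")
    return volume_ml / config.max_flow_ml_min * 60.0


def schedule_ratio_flow(
    sample_volume_ml: float,
    ratio_diluent_to_sample: float,
    sample_pump: PumpConfig | None = None,
    diluent_pump: PumpConfig | None = None,
    co_flow: bool = True,
) -> FlowPlan:
    """Plan coordinated pump flows at a diluent:sample ratio.

    In co-flow mode both pumps run for the same duration with
    ``Q_diluent / Q_sample = ratio``; the binding pump runs at its maximum and
    the other is scaled down, so no rate ever exceeds its limit. Sequentially
    (``co_flow=False``) each pump runs at its own maximum for its own
    duration.
    """
    if sample_volume_ml <= 0:
        raise InvalidInputError("sample_volume must be positive")
    if ratio_diluent_to_sample < 0:
        raise InvalidInputError("ratio must be nonnegative")
    sp = sample_pump or PumpConfig(pump_id="sample")
    dp = diluent_pump or PumpConfig(pump_id="diluent")
    ratio = ratio_diluent_to_sample
    diluent_volume_ml = ratio * sample_volume_ml

    if co_flow and ratio > 0:
        q_sample = min(sp.max_flow_ml_min, dp.max_flow_ml_min / ratio)
        q_diluent = ratio * q_sample
        duration = sample_volume_ml / q_sample * 60.0
        durations = (duration, duration)
    else:
        q_sample = sp.max_flow_ml_min
        q_diluent = dp.max_flow_ml_min if ratio > 0 else 0.0
        durations = (
            max_rate_time(sample_volume_ml, sp),
            max_rate_time(diluent_volume_ml, dp) if ratio > 0 else 0.0,
        )

    assert q_sample <= sp.max_flow_ml_min + _RATE_EPS
    assert q_diluent <= dp.max_flow_ml_min + _RATE_EPS

    s_steps = steps_for_volume(sample_volume_ml, sp)
    d_steps = steps_for_volume(diluent_volume_ml, dp)
    return FlowPlan(
        sample=PumpChannelPlan(
            sp.pump_id, q_sample, durations[0], s_steps, sample_volume_ml,
            delivered_volume_ml(s_steps, sp),
        ),
        diluent=PumpChannelPlan(
            dp.pump_id, q_diluent, durations[1], d_steps, diluent_volume_ml,
            delivered_volume_ml(d_steps, dp),
        ),
        ratio_requested=ratio,
        co_flow=co_flow,
    )
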