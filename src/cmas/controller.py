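"""Finite-state-machine workflow control and the processing-time model.

One run walks the fixed graph

    IDLE -> PRIME -> MEASURE -> COMPUTE -> DILUTE -> FLUSH -> DONE

with every non-terminal state able to fall into ERROR (saturated reading,
out-of-range estimate, target above measured concentration, ...). DONE and
ERROR re-arm to IDLE. Timestamps are simulated — deterministic accumulation
of stage durations — so runs are bit-reproducible; wall-clock time never
enters.

The throughput model: manual processing of one sample averages 288 s
(12.5 samples/h) regardless of volume, while automated processing takes
``fixed_overhead + per_ml * V`` seconds with the sample pump at its maximum
rate. The 50 s default overhead decomposes as 30 s tubing replacement plus
20 s priming; break-even with the manual reference falls at about 4.3 mL.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import optics
from .calibration import CalibrationCurve, RangeFlag, estimate_concentration, invert
from .dilution import DilutionPlan, Solution, mix, plan_dilution
from .errors import CannotConcentrateError, InvalidInputError
from .pumping import FlowPlan, PumpConfig, schedule_ratio_flow
from .twin import TwinConfig

__all__ = [
    "WorkflowState",
    "Trigger",
    "TRANSITIONS",
    "step",
    "Event",
    "RunRecord",
    "TimingModel",
    "run_workflow",
    "estimate_processing_time",
    "break_even_volume",
    "throughput",
]


class WorkflowState(enum.Enum):
    IDLE = "IDLE"
    PRIME = "PRIME"
    MEASURE = "MEASURE"
    COMPUTE = "COMPUTE"
    DILUTE = "DILUTE"
    FLUSH = "FLUSH"
    DONE = "DONE"
    ERROR = "ERROR"


class Trigger(enum.Enum):
    START = "start"
    PRIMED = "primed"
    MEASUREMENT_COMPLETE = "measurement_complete"
    PLAN_READY = "plan_ready"
    DILUTION_COMPLETE = "dilution_complete"
    FLUSH_COMPLETE = "flush_complete"
    RESET = "reset"
    FAULT = "fault"


#: The complete transition table. Undefined (state, trigger) pairs resolve to
#: ERROR in :func:`step`; there are deliberately no other edges, which keeps
#: the graph acyclic apart from the explicit RESET re-arm.
TRANSITIONS: dict[tuple[WorkflowState, Trigger], WorkflowState] = {
    (WorkflowState.IDLE, Trigger.START): WorkflowState.PRIME,
    (WorkflowState.PRIME, Trigger.PRIMED): WorkflowState.MEASURE,
    (WorkflowState.MEASURE, Trigger.MEASUREMENT_COMPLETE): WorkflowState.COMPUTE,
    (WorkflowState.COMPUTE, Trigger.PLAN_READY): WorkflowState.DILUTE,
    (WorkflowState.DILUTE, Trigger.DILUTION_COMPLETE): WorkflowState.FLUSH,
    (WorkflowState.FLUSH, Trigger.FLUSH_COMPLETE): WorkflowState.DONE,
    (WorkflowState.DONE, Trigger.RESET): WorkflowState.IDLE,
    (WorkflowState.ERROR, Trigger.RESET): WorkflowState.IDLE,
}


def step(current: WorkflowState, trigger: Trigger) -> WorkflowState:
    """Advance the FSM; any undefined (state, trigger) pair lands in ERROR.

    ERROR is a state, not an exception — faults never raise out of the
    control loop, which is what prevents the firmware from wedging.
    """
    return TRANSITIONS.get((current, trigger), WorkflowState.ERROR)


@dataclass(frozen=True)
class Event:
    timestamp_s: float
    state: WorkflowState
    message: str = ""

    def to_json_line(self) -> str:
        return json.dumps(
            {"timestamp_s": self.timestamp_s, "state": self.state.value, "message": self.message}
        )


@dataclass(frozen=True)
class TimingModel:
    """Affine processing-time model: ``t(V) = fixed + per_ml * V`` seconds.

    The fixed term splits into tubing replacement (30 s, skippable when
    cross-contamination is acceptable) and priming (20 s). ``manual_reference_s``
    is the benchmark manual processing time per sample (288 s).
    """

    tubing_replacement_s: float = 30.0
    priming_s: float = 20.0
    per_ml_s: float = 55.0
    manual_reference_s: float = 288.0
    measure_duration_s: float = 10.0
    flush_duration_s: float | None = None  # defaults to priming_s

    def __post_init__(self) -> None:
        if min(self.tubing_replacement_s, self.priming_s, self.per_ml_s, self.manual_reference_s) < 0:
            raise InvalidInputError("timing parameters must be nonnegative")

    @property
    def fixed_overhead_s(self) -> float:
        return self.tubing_replacement_s + self.priming_s

    @property
    def flush_s(self) -> float:
        return self.priming_s if self.flush_duration_s is None else self.flush_duration_s


def estimate_processing_time(
    volume_ml: float, model: TimingModel | None = None, include_tubing_change: bool = True
) -> float:
    """Seconds to process one sample of a given volume at maximum pump rate."""
    if volume_ml < 0:
        raise InvalidInputError("volume must be nonnegative")
    m = model or TimingModel()
    fixed = m.priming_s + (m.tubing_replacement_s if include_tubing_change else 0.0)
    return fixed + m.per_ml_s * volume_ml


def break_even_volume(model: TimingModel | None = None) -> float:
    """Sample volume at which automated and manual processing take equal time."""
    m = model or TimingModel()
    return (m.manual_reference_s - m.fixed_overhead_s) / m.per_ml_s


def throughput(manual_seconds: float) -> float:
    """Samples per hour at a given per-sample processing time."""
    if manual_seconds <= 0:
        raise InvalidInputError("processing time must be positive")
    return 3600.0 / manual_seconds


@dataclass
class RunRecord:
    """Timestamped trace of one measure -> compute -> dilute workflow."""

    events: list[Event] = field(default_factory=list)
    plan: DilutionPlan | None = None
    flow_plan: FlowPlan | None = None
    measured_concentration: float | None = None
    achieved_concentration: float | None = None
    final_state: WorkflowState = WorkflowState.IDLE

    @property
    def elapsed_s(self) -> float:
        if not self.events:
            return 0.0
        return self.events[-1].timestamp_s - self.events[0].timestamp_s

    def validate(self) -> None:
        """Assert the event-log invariants (nondecreasing times, proper endpoints)."""
        if not self.events:
            raise InvalidInputError("run record has no events")
        times = [e.timestamp_s for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise InvalidInputError("event timestamps must be nondecreasing")
        if self.events[0].state is not WorkflowState.IDLE:
            raise InvalidInputError("first event must be IDLE entry")
        if self.events[-1].state not in (WorkflowState.DONE, WorkflowState.ERROR):
            raise InvalidInputError("last event must be DONE or ERROR entry")

    def events_jsonl(self, path: str | Path | None = None) -> str:
        payload = "\n".join(e.to_json_line() for e in self.events)
        if path is not None:
            Path(path).write_text(payload + "\n", encoding="utf-8")
        return payload

    def summary_dict(self) -> dict:
        return {
            "final_state": self.final_state.value,
            "measured_concentration": self.measured_concentration,
            "achieved_concentration": self.achieved_concentration,
            "elapsed_s": self.elapsed_s,
            "plan": self.plan.to_dict() if self.plan else None,
            "n_events": len(self.events),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.summary_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n", encoding="utf-8")
        return payload


def run_workflow(
    sample: Solution,
    c_target: float,
    curve: CalibrationCurve,
    optics_config: optics.OpticalConfig | None = None,
    sample_pump: PumpConfig | None = None,
    diluent_pump: PumpConfig | None = None,
    twin: TwinConfig | None = None,
    timing: TimingModel | None = None,
    diluent_cpa_pct: float = 0.0,
) -> RunRecord:
    """Execute one full measure -> compute -> dilute run on the digital twin.

    Faults (saturated or out-of-range measurement, target above measured
    concentration) terminate in the ERROR state with a message; no exception
    escapes. Timestamps are simulated from the timing model's stage
    durations.
    """
    cfg = optics_config or optics.OpticalConfig()
    tw = twin or TwinConfig(noise_sd=0.0, loss_fraction=0.0, rng_seed=0)
    cfg = cfg.with_(adc_quantize=tw.adc_quantize)
    tm = timing or TimingModel()
    sp = sample_pump or PumpConfig(pump_id="sample")
    dp = diluent_pump or PumpConfig(pump_id="diluent")
    rng = tw.rng()

    record = RunRecord()
    t = 0.0
    state = WorkflowState.IDLE
    record.events.append(Event(t, state, "run armed"))

    def fail(message: str) -> RunRecord:
        record.events.append(Event(t, WorkflowState.ERROR, message))
        record.final_state = WorkflowState.ERROR
        return record

    state = step(state, Trigger.START)
    record.events.append(Event(t, state, "priming tubing"))
    t += tm.priming_s

    state = step(state, Trigger.PRIMED)
    record.events.append(Event(t, state, "measuring sample"))
    reading = optics.sensor_voltage(
        sample.concentration, curve, cfg, noise_sd=tw.noise_sd, rng=rng, timestamp_s=t
    )
    t += tm.measure_duration_s
    status = optics.saturation_check(reading, cfg)
    if status is not optics.SaturationStatus.OK:
        return fail(f"saturated measurement ({status.value}) at {reading.voltage:.3f} V")
    c_measured, flag = estimate_concentration(invert(curve), reading.voltage, curve)
    record.measured_concentration = c_measured
    if flag is not RangeFlag.IN_RANGE:
        return fail(
            f"measured concentration {c_measured:.3g} cells/mL is {flag.value} "
            f"of the calibration validity range"
        )

    state = step(state, Trigger.MEASUREMENT_COMPLETE)
    record.events.append(Event(t, state, "computing dilution plan"))
    try:
        plan = plan_dilution(c_measured, c_target, sample.volume_ml)
    except CannotConcentrateError as exc:
        return fail(str(exc))
    record.plan = plan

    state = step(state, Trigger.PLAN_READY)
    flow = schedule_ratio_flow(plan.sample_volume_ml, plan.flow_ratio, sp, dp)
    record.flow_plan = flow
    record.events.append(
        Event(t, state, f"dilution factor {plan.factor_d:.4g}, flow ratio {plan.flow_ratio:.4g}")
    )
    t += max(flow.sample.duration_s, flow.diluent.duration_s)
    diluent = Solution(0.0, plan.diluent_volume_ml, diluent_cpa_pct)
    mixed = mix([Solution(sample.concentration, plan.sample_volume_ml, sample.cpa_pct), diluent])
    record.achieved_concentration = mixed.concentration * (1.0 - tw.loss_fraction)

    state = step(state, Trigger.DILUTION_COMPLETE)
    record.events.append(Event(t, state, "flushing fluid path"))
    t += tm.flush_s

    state = step(state, Trigger.FLUSH_COMPLETE)
    record.events.append(Event(t, state, "run complete"))
    record.final_state = state
    return record
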