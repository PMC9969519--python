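"""Dilution planning with cryoprotectant tracking.

A sample measured at concentration ``c_measured`` is brought to a target by
adding diluent at the dilution factor ``D = c_measured / c_target``; the
diluent:sample flow ratio is ``D - 1``. The device can only add diluent, so a
target above the measured concentration is an error.

The two-stage cryopreservation workflow first dilutes raw sample to an
intermediate concentration with isotonic extender, then mixes 1:1 with a
double-strength cryoprotectant (CPA) medium, exactly halving both the cell
concentration and the CPA fraction (e.g. 2e9 cells/mL + 20% CPA medium ->
1e9 cells/mL at 10% CPA). Mixing is ideal: cell count and CPA volume are
both conserved, with no partial-volume corrections.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

from .errors import CannotConcentrateError, InvalidInputError

__all__ = ["Solution", "DilutionPlan", "TwoStagePlan", "plan_dilution", "mix", "plan_two_stage"]


@dataclass(frozen=True)
class Solution:
    """A fluid with cell concentration (cells/mL), volume (mL) and CPA fraction (% v/v)."""

    concentration: float
    volume_ml: float
    cpa_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.concentration < 0 or self.volume_ml < 0:
            raise InvalidInputError("concentration and volume must be nonnegative")
        if not 0 <= self.cpa_pct <= 100:
            raise InvalidInputError("cpa_pct must be within [0, 100]")

    @property
    def cells(self) -> float:
        return self.concentration * self.volume_ml


@dataclass(frozen=True)
class DilutionPlan:
    c_measured: float
    c_target: float
    sample_volume_ml: float

    def __post_init__(self) -> None:
        if self.c_measured <= 0 or self.c_target <= 0 or self.sample_volume_ml <= 0:
            raise InvalidInputError("concentrations and volume must be positive")
        if self.c_measured < self.c_target:
            raise CannotConcentrateError(
                f"measured {self.c_measured:g} cells/mL is below target "
                f"{self.c_target:g}; the device can only dilute"
            )

    @property
    def factor_d(self) -> float:
        """Dilution factor D = c_measured / c_target (>= 1)."""
        return self.c_measured / self.c_target

    @property
    def flow_ratio(self) -> float:
        """Diluent:sample flow ratio, D - 1."""
        return self.factor_d - 1.0

    @property
    def diluent_volume_ml(self) -> float:
        return self.sample_volume_ml * self.flow_ratio

    @property
    def expected_output_volume_ml(self) -> float:
        return self.sample_volume_ml * self.factor_d

    def to_dict(self) -> dict:
        return {
            **asdict(self),
            "factor_d": self.factor_d,
            "flow_ratio": self.flow_ratio,
            "diluent_volume_ml": self.diluent_volume_ml,
            "expected_output_volume_ml": self.expected_output_volume_ml,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n", encoding="utf-8")
        return payload


def plan_dilution(c_measured: float, c_target: float, sample_volume_ml: float) -> DilutionPlan:
    """Compute the dilution factor, flow ratio and volumes to hit a target concentration."""
    return DilutionPlan(c_measured=c_measured, c_target=c_target, sample_volume_ml=sample_volume_ml)


def mix(parts: Sequence[Solution]) -> Solution:
    """Ideal mixing: volumes add; cells and CPA volume are conserved."""
    parts = list(parts)
    if not parts:
        raise InvalidInputError("cannot mix an empty list of solutions")
    total_v = sum(p.volume_ml for p in parts)
    if total_v <= 0:
        raise InvalidInputError("total volume must be positive")
    return Solution(
        concentration=sum(p.cells for p in parts) / total_v,
        volume_ml=total_v,
        cpa_pct=sum(p.cpa_pct * p.volume_ml for p in parts) / total_v,
    )


@dataclass(frozen=True)
class TwoStagePlan:
    """Extender dilution to an intermediate target, then fixed 1:1 CPA addition."""

    stage1: DilutionPlan
    cpa_double_strength_pct: float

    @property
    def stage2(self) -> DilutionPlan:
        return DilutionPlan(
            c_measured=self.stage1.c_target,
            c_target=self.stage1.c_target / 2.0,
            sample_volume_ml=self.stage1.expected_output_volume_ml,
        )

    @property
    def final_concentration(self) -> float:
        return self.stage1.c_target / 2.0

    @property
    def final_cpa_pct(self) -> float:
        return self.cpa_double_strength_pct / 2.0

    @property
    def final_volume_ml(self) -> float:
        return self.stage2.expected_output_volume_ml

    def to_dict(self) -> dict:
        return {
            "stage1": self.stage1.to_dict(),
            "stage2": self.stage2.to_dict(),
            "cpa_double_strength_pct": self.cpa_double_strength_pct,
            "final_concentration": self.final_concentration,
            "final_cpa_pct": self.final_cpa_pct,
            "final_volume_ml": self.final_volume_ml,
        }


def plan_two_stage(
    c_raw: float,
    intermediate_target: float,
    cpa_double_strength_pct: float,
    sample_volume_ml: float,
) -> TwoStagePlan:
    """Plan the two-stage extender + double-strength-CPA protocol.

    Stage 1 dilutes raw sample to ``intermediate_target`` with extender;
    stage 2 mixes the result 1:1 with CPA medium at
    ``cpa_double_strength_pct``, so the final concentration is
    ``intermediate_target / 2`` and the final CPA fraction is half the
    double-strength value.
    """
    if not 0 <= cpa_double_strength_pct <= 100:
        raise InvalidInputError("cpa_double_strength_pct must be within [0, 100]")
    stage1 = plan_dilution(c_raw, intermediate_target, sample_volume_ml)
    return TwoStagePlan(stage1=stage1, cpa_double_strength_pct=cpa_double_strength_pct)
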