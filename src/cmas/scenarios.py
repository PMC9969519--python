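"""Packaged reference curves and replayable study scenarios.

The two published calibration curves — channel catfish sperm measured from a
1:1 serial dilution starting at 4.0e9 cells/mL, and *Tetraselmis chuii*
algae starting at 3.6e6 cells/mL — plus the bench-spectrophotometer
percent-transmittance reference, are shipped as constants so the twin can
regenerate the corresponding experiments. Scenario files (YAML) describe
custom curve/series/twin combinations for the fixture-generator CLI.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .calibration import CalibrationCurve, DilutionSeriesSpec
from .errors import InvalidInputError
from .twin import TrialResult, TwinConfig, generate_calibration_dataset, simulate_auto_dilution

__all__ = [
    "SPERM_CURVE",
    "ALGAE_CURVE",
    "NANODROP_REFERENCE_CURVE",
    "SPERM_SERIES",
    "ALGAE_SERIES",
    "DEFAULT_SCENARIO_TWIN",
    "builtin_scenarios",
    "scenario_from_dict",
    "load_scenario",
    "generate_scenario_dataset",
    "replay_auto_dilution",
]

# Published log-linear calibrations (voltage on log10 cells/mL).
SPERM_CURVE = CalibrationCurve(
    slope_a=-1.9658, intercept_b=19.702, c_min=1e8, c_max=4.0e9,
    r_squared=0.9937, label="channel catfish sperm",
)
ALGAE_CURVE = CalibrationCurve(
    slope_a=-2.9698, intercept_b=20.94, c_min=3e5, c_max=3.6e6,
    r_squared=0.9812, label="Tetraselmis chuii algae",
)
# Bench spectrophotometer reference: percent transmittance on log10 cells/mL.
NANODROP_REFERENCE_CURVE = CalibrationCurve(
    slope_a=-35.358, intercept_b=298.92, c_min=3e5, c_max=3.6e6,
    r_squared=0.8429, label="Nanodrop %T reference",
)

SPERM_SERIES = DilutionSeriesSpec(start_concentration=4.0e9, n_samples=10, ratio=2.0)
ALGAE_SERIES = DilutionSeriesSpec(start_concentration=3.6e6, n_samples=8, ratio=2.0)

#: Imperfection model used by the packaged auto-dilution scenarios: 0.02 V
#: voltage noise and 15% per-pass cell loss (magnitude chosen as a plausible
#: mid-range for tubing adhesion; the mechanism is not modelled).
DEFAULT_SCENARIO_TWIN = TwinConfig(noise_sd=0.02, loss_fraction=0.15, rng_seed=0)


def builtin_scenarios(seed: int = 0) -> dict[str, dict[str, Any]]:
    """Named calibration-dataset scenarios mirroring the reference experiments."""
    return {
        "sperm_calibration": {
            "curve": SPERM_CURVE,
            "series": SPERM_SERIES,
            "n_pulls": 4,
            "twin": TwinConfig(noise_sd=0.02, loss_fraction=0.0, rng_seed=seed),
        },
        "algae_calibration": {
            "curve": ALGAE_CURVE,
            "series": ALGAE_SERIES,
            "n_pulls": 4,
            "twin": TwinConfig(noise_sd=0.02, loss_fraction=0.0, rng_seed=seed),
        },
    }


def scenario_from_dict(raw: dict[str, Any]) -> dict[str, Any]:
    """Build scenario objects (curve, series, twin, n_pulls) from plain mappings."""
    try:
        curve = CalibrationCurve(**raw["curve"])
        series = DilutionSeriesSpec(**raw["series"])
    except (KeyError, TypeError) as exc:
        raise InvalidInputError(f"malformed scenario: {exc}") from exc
    twin = TwinConfig(**raw.get("twin", {}))
    return {"curve": curve, "series": series, "twin": twin, "n_pulls": int(raw.get("n_pulls", 4))}


def load_scenario(path: str | Path) -> dict[str, Any]:
    """Load a YAML scenario file (keys: curve, series, twin, n_pulls)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise InvalidInputError(f"scenario file {path} does not contain a mapping")
    return scenario_from_dict(raw)


def generate_scenario_dataset(scenario: dict[str, Any]) -> pd.DataFrame:
    """Run the twin's calibration-dataset generator for one scenario."""
    return generate_calibration_dataset(
        scenario["curve"], scenario["series"], scenario["n_pulls"], scenario["twin"]
    )


def replay_auto_dilution(
    seed: int = 0, twin: TwinConfig | None = None, n_trials: int = 5
) -> dict[str, TrialResult]:
    """Replay the automatic-dilution trials: algae to 1e6 cells/mL.

    Five trials each from the culture concentration (3.6e6 cells/mL) and from
    a 1:1 pre-dilution of it (1.8e6 cells/mL), under the default twin noise
    and loss model. Returns results keyed ``low_start`` and ``high_start``.
    """
    base = twin or DEFAULT_SCENARIO_TWIN
    return {
        "low_start": simulate_auto_dilution(
            1.8e6, 1.0e6, n_trials, base.with_(rng_seed=seed), ALGAE_CURVE
        ),
        "high_start": simulate_auto_dilution(
            3.6e6, 1.0e6, n_trials, base.with_(rng_seed=seed + 1), ALGAE_CURVE
        ),
    }
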