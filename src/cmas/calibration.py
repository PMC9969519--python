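"""Range-restricted log-linear calibration curves and their inverse estimators.

Turbidimetric sensors respond approximately linearly in log10 cell
concentration over a limited range: ``voltage = a * log10(c) + b`` with
``a < 0`` (denser samples transmit less light). Below a lower validity bound
``c_min`` the response flattens into a plateau and concentrations become
indistinguishable; the fit is therefore restricted to points at or above
``c_min``, and estimates outside ``[c_min, c_max]`` are flagged rather than
trusted.

The fitting surface follows the statsmodels model/results convention:
:class:`CalibrationModel` holds the data and fit options, ``fit()`` returns a
:class:`CalibrationFit` carrying the curve, standard errors, diagnostics and a
``summary()`` table. The same machinery fits percent-transmittance reference
data from a bench spectrophotometer for method comparison.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .display import round_half_up
from .errors import InsufficientDataError, InvalidInputError, NonInvertibleCurveError

__all__ = [
    "CONCENTRATION_COL",
    "VOLTAGE_COL",
    "TRANSMITTANCE_COL",
    "REPLICATE_COL",
    "RangeFlag",
    "CalibrationCurve",
    "EstimatorCoefficients",
    "DilutionSeriesSpec",
    "CalibrationModel",
    "CalibrationFit",
    "fit_loglinear",
    "fit_transmittance_reference",
    "invert",
    "rounded_estimator",
    "estimate_concentration",
    "make_dilution_series",
    "absorbance_to_transmittance",
]

CONCENTRATION_COL = "concentration_cells_per_ml"
VOLTAGE_COL = "voltage_v"
TRANSMITTANCE_COL = "transmittance_pct"
REPLICATE_COL = "replicate"


class RangeFlag(enum.Enum):
    """Where an estimated concentration falls relative to the curve's validity range."""

    IN_RANGE = "in_range"
    BELOW_RANGE = "below_range"
    ABOVE_RANGE = "above_range"


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted log-linear map ``response = slope_a * log10(c) + intercept_b``.

    Parameters
    ----------
    slope_a : float
        Slope in response units per decade of concentration; negative.
    intercept_b : float
        Intercept in response units (volts, or %T for reference curves).
    c_min, c_max : float
        Validity range in cells/mL; estimates outside it are flagged.
    r_squared : float
        Coefficient of determination of the generating fit.
    label : str
        Free-text description of the sample type / instrument.
    """

    slope_a: float
    intercept_b: float
    c_min: float
    c_max: float
    r_squared: float = float("nan")
    label: str = ""

    def __post_init__(self) -> None:
        if not self.slope_a < 0:
            raise InvalidInputError(f"slope_a must be negative, got {self.slope_a}")
        if not 0 < self.c_min < self.c_max:
            raise InvalidInputError(
                f"need 0 < c_min < c_max, got c_min={self.c_min}, c_max={self.c_max}"
            )
        if not math.isnan(self.r_squared) and not 0 <= self.r_squared <= 1:
            raise InvalidInputError(f"r_squared outside [0, 1]: {self.r_squared}")

    def response_at(self, concentration: float) -> float:
        """Ideal (unclamped) response at a concentration inside the validity range."""
        if concentration <= 0:
            raise InvalidInputError("concentration must be positive")
        return self.slope_a * math.log10(concentration) + self.intercept_b

    def invert(self) -> "EstimatorCoefficients":
        return invert(self)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n", encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationCurve":
        text = Path(source).read_text(encoding="utf-8") if isinstance(source, Path) else source
        if isinstance(source, str) and not source.lstrip().startswith("{"):
            text = Path(source).read_text(encoding="utf-8")
        return cls(**json.loads(text))


@dataclass(frozen=True)
class EstimatorCoefficients:
    """Inverse-prediction coefficients: ``c = 10 ** (inv_intercept - inv_slope * v)``."""

    inv_intercept: float
    inv_slope: float

    def __post_init__(self) -> None:
        if not self.inv_slope > 0:
            raise InvalidInputError("inv_slope must be positive")

    def concentration(self, voltage: float) -> float:
        return 10.0 ** (self.inv_intercept - self.inv_slope * voltage)


@dataclass(frozen=True)
class DilutionSeriesSpec:
    """A geometric serial-dilution series (default 1:1 steps, i.e. ratio 2)."""

    start_concentration: float
    n_samples: int
    ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.start_concentration <= 0:
            raise InvalidInputError("start_concentration must be positive")
        if self.n_samples < 1:
            raise InvalidInputError("n_samples must be >= 1")
        if self.ratio <= 1:
            raise InvalidInputError("ratio must be > 1")

    def concentrations(self) -> np.ndarray:
        return make_dilution_series(self)


def invert(curve: CalibrationCurve) -> EstimatorCoefficients:
    """Exact inverse of a fitted curve: solve ``v = a log10 c + b`` for ``c``.

    ``log10 c = (b - v)/|a| = b/|a| - v/|a|``, giving ``inv_intercept = b/|a|``
    and ``inv_slope = 1/|a|``.
    """
    if curve.slope_a >= 0:
        raise NonInvertibleCurveError("curve slope must be negative to invert")
    mag = abs(curve.slope_a)
    return EstimatorCoefficients(inv_intercept=curve.intercept_b / mag, inv_slope=1.0 / mag)


def rounded_estimator(
    curve: CalibrationCurve,
    coefficient_decimals: int = 2,
    slope_decimals: int = 3,
    intercept_decimals: int = 2,
) -> EstimatorCoefficients:
    """Inverse estimator at report precision, as deployed on instrument firmware.

    The regression coefficients are first rounded half-up to the precision at
    which they are reported (2 decimals), then inverted, then the inverse
    coefficients are rounded half-up again. This two-step rounding is how the
    deployed constants (e.g. 0.508, 10 and 0.337, 7.05) arise from the fitted
    curves; inverting at full precision and rounding once does not reproduce
    them.
    """
    a = round_half_up(curve.slope_a, coefficient_decimals)
    b = round_half_up(curve.intercept_b, coefficient_decimals)
    mag = abs(a)
    return EstimatorCoefficients(
        inv_intercept=round_half_up(b / mag, intercept_decimals),
        inv_slope=round_half_up(1.0 / mag, slope_decimals),
    )


# relative guard band on the validity bounds: a plateau reading inverts to
# ~c_min exactly, and such a sample is indistinguishable from one below the
# range, so the lower bound is inclusive (up to floating-point round-trip).
_RANGE_GUARD = 1e-9


def estimate_concentration(
    est: EstimatorCoefficients, voltage: float, curve: CalibrationCurve
) -> tuple[float, RangeFlag]:
    """Inverse-predict a concentration from a sensor reading and flag range violations."""
    if not math.isfinite(voltage):
        raise InvalidInputError("voltage must be finite")
    c = est.concentration(voltage)
    if c <= curve.c_min * (1.0 + _RANGE_GUARD):
        flag = RangeFlag.BELOW_RANGE
    elif c > curve.c_max * (1.0 + _RANGE_GUARD):
        flag = RangeFlag.ABOVE_RANGE
    else:
        flag = RangeFlag.IN_RANGE
    return c, flag


def make_dilution_series(spec: DilutionSeriesSpec) -> np.ndarray:
    """Exact nominal concentrations of a serial-dilution series, highest first.

    Element k is ``start / ratio**k``; rendering at 2 significant figures is
    presentation-layer only (see :func:`cmas.display.format_concentration`).
    """
    k = np.arange(spec.n_samples)
    return spec.start_concentration / spec.ratio**k


def absorbance_to_transmittance(absorbance: float | np.ndarray) -> float | np.ndarray:
    """Convert absorbance (AU) to percent transmittance: %T = 10**(2 - A)."""
    return 10.0 ** (2.0 - np.asarray(absorbance, dtype=float)) if np.ndim(absorbance) else 10.0 ** (
        2.0 - float(absorbance)
    )


def _as_dataframe(
    points: pd.DataFrame | Iterable, response: str
) -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        df = points.copy()
    else:
        rows = list(points)
        if rows and isinstance(rows[0], dict):
            df = pd.DataFrame(rows)
        else:
            cols = [CONCENTRATION_COL, response, REPLICATE_COL]
            df = pd.DataFrame(rows, columns=cols[: len(rows[0])] if rows else cols)
    if CONCENTRATION_COL not in df or response not in df:
        raise InvalidInputError(
            f"calibration data needs columns '{CONCENTRATION_COL}' and '{response}'"
        )
    if (df[CONCENTRATION_COL] <= 0).any():
        raise InvalidInputError("all concentrations must be positive")
    return df


class CalibrationModel:
    """Ordinary least squares of sensor response on log10 cell concentration.

    Only points with ``concentration >= c_min`` enter the fit; plateau points
    below the bound would bias the line and depress r². Replicates enter as
    separate points (no pre-averaging).

    Parameters
    ----------
    data : DataFrame
        Columns ``concentration_cells_per_ml``, the response column, and
        optionally ``replicate``.
    c_min : float
        Lower validity bound in cells/mL restricting the fit.
    response : str
        Response column: ``voltage_v`` (default) or ``transmittance_pct``.
    label : str
        Carried onto the fitted curve.
    """

    def __init__(
        self,
        data: pd.DataFrame | Iterable,
        c_min: float,
        response: str = VOLTAGE_COL,
        label: str = "",
    ) -> None:
        if c_min <= 0:
            raise InvalidInputError("c_min must be positive")
        self.data = _as_dataframe(data, response)
        self.c_min = float(c_min)
        self.response = response
        self.label = label

    @classmethod
    def from_csv(
        cls, path: str | Path, c_min: float, response: str = VOLTAGE_COL, label: str = ""
    ) -> "CalibrationModel":
        """Read calibration points from CSV (UTF-8, '.' decimal, one point per row)."""
        return cls(pd.read_csv(path), c_min=c_min, response=response, label=label)

    @classmethod
    def from_points(
        cls,
        concentration: Sequence[float],
        response_values: Sequence[float],
        c_min: float,
        replicate: Sequence[int] | None = None,
        response: str = VOLTAGE_COL,
        label: str = "",
    ) -> "CalibrationModel":
        df = pd.DataFrame({CONCENTRATION_COL: concentration, response: response_values})
        if replicate is not None:
            df[REPLICATE_COL] = replicate
        return cls(df, c_min=c_min, response=response, label=label)

    def fit(self) -> "CalibrationFit":
        included = self.data[self.data[CONCENTRATION_COL] >= self.c_min]
        if included[CONCENTRATION_COL].nunique() < 2:
            raise InsufficientDataError(
                "need at least 2 distinct concentrations at or above c_min "
                f"({self.c_min:g} cells/mL); have {included[CONCENTRATION_COL].nunique()}"
            )
        x = np.log10(included[CONCENTRATION_COL].to_numpy(dtype=float))
        y = included[self.response].to_numpy(dtype=float)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        return CalibrationFit(self, res, included)


@dataclass
class CalibrationFit:
    """Results of a range-restricted log-linear calibration fit."""

    model: CalibrationModel
    _sm_results: "sm.regression.linear_model.RegressionResultsWrapper"
    _included: pd.DataFrame = field(repr=False)

    @property
    def slope_a(self) -> float:
        return float(self._sm_results.params[1])

    @property
    def intercept_b(self) -> float:
        return float(self._sm_results.params[0])

    @property
    def slope_se(self) -> float:
        return float(self._sm_results.bse[1])

    @property
    def intercept_se(self) -> float:
        return float(self._sm_results.bse[0])

    @property
    def rsquared(self) -> float:
        return float(self._sm_results.rsquared)

    @property
    def nobs(self) -> int:
        return int(self._sm_results.nobs)

    @property
    def n_excluded(self) -> int:
        return len(self.model.data) - self.nobs

    @property
    def c_min(self) -> float:
        return self.model.c_min

    @property
    def c_max(self) -> float:
        return float(self._included[CONCENTRATION_COL].max())

    @property
    def curve(self) -> CalibrationCurve:
        return CalibrationCurve(
            slope_a=self.slope_a,
            intercept_b=self.intercept_b,
            c_min=self.c_min,
            c_max=self.c_max,
            r_squared=min(max(self.rsquared, 0.0), 1.0),
            label=self.model.label,
        )

    def invert(self) -> EstimatorCoefficients:
        return invert(self.curve)

    def estimate(self, voltage: float) -> tuple[float, RangeFlag]:
        return estimate_concentration(self.invert(), voltage, self.curve)

    def summary(self) -> str:
        unit = "V" if self.model.response == VOLTAGE_COL else "%T"
        est = self.invert()
        lines = [
            "Log-linear calibration fit" + (f" [{self.model.label}]" if self.model.label else ""),
            "=" * 58,
            f"response = slope * log10(concentration) + intercept  [{unit}]",
            f"slope      {self.slope_a: .6g}  (SE {self.slope_se:.3g})",
            f"intercept  {self.intercept_b: .6g}  (SE {self.intercept_se:.3g})",
            f"r-squared  {self.rsquared:.4f}",
            f"points     {self.nobs} used, {self.n_excluded} below c_min excluded",
            f"validity   [{self.c_min:.3g}, {self.c_max:.3g}] cells/mL",
            f"inverse    c = 10^({est.inv_intercept:.6g} - {est.inv_slope:.6g} * reading)",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of all points plus the fitted line over the validity range."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.model.data
        ax.semilogx(
            df[CONCENTRATION_COL], df[self.model.response], "x", color="0.3", label="data"
        )
        grid = np.logspace(math.log10(self.c_min), math.log10(self.c_max), 50)
        ax.semilogx(grid, self.slope_a * np.log10(grid) + self.intercept_b, "-", label="fit")
        ax.axvline(self.c_min, ls=":", color="0.6")
        ax.set_xlabel("cell concentration (cells/mL)")
        ax.set_ylabel("sensor voltage (V)" if self.model.response == VOLTAGE_COL else "%T")
        ax.legend()
        return ax


def fit_loglinear(
    points: pd.DataFrame | Iterable, c_min: float, label: str = ""
) -> CalibrationFit:
    """Fit voltage on log10 concentration restricted to ``concentration >= c_min``."""
    return CalibrationModel(points, c_min=c_min, label=label).fit()


def fit_transmittance_reference(
    points: pd.DataFrame | Iterable, c_min: float, label: str = ""
) -> CalibrationFit:
    """Fit a spectrophotometer %T reference curve (same OLS, %T response)."""
    return CalibrationModel(points, c_min=c_min, response=TRANSMITTANCE_COL, label=label).fit()
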