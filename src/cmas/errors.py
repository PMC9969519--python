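"""Exception hierarchy for the cmas package."""


class CmasError(Exception):
    """Base class for all cmas errors."""


class InvalidInputError(CmasError, ValueError):
    """An argument violates a precondition (negative volume, empty list, ...)."""


class CalibrationFailureError(CmasError):
    """Baseline calibration could not reach the target voltage within tolerance."""


class InsufficientDataError(CmasError):
    """Too few distinct in-range points to fit a calibration curve."""


class NonInvertibleCurveError(CmasError):
    """The calibration curve has a non-negative slope and cannot be inverted."""


class CannotConcentrateError(CmasError):
    """The measured concentration is below the target; the device can only dilute."""
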