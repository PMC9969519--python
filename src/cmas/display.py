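"""Presentation-layer rounding helpers.

Internal computation is always full precision; these helpers exist only to
render numbers at report precision. Two conventions are used: half-up
rounding (the default for times, volumes and coefficients) and truncation
toward zero. Both are implemented with ``decimal`` on ``repr(x)`` so the
results are platform-independent and free of binary floating-point ties.
"""

from __future__ import annotations

from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "truncate", "round_sig", "format_concentration"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero (286.5 -> 287)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def truncate(x: float, ndigits: int = 0) -> float:
    """Truncate toward zero at ``ndigits`` decimals (0.50870 -> 0.508)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_DOWN))


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half-up (7812500 -> 7.8e6)."""
    if x == 0:
        return 0.0
    d = Decimal(repr(float(x)))
    shift = sig - 1 - d.adjusted()
    q = Decimal(1).scaleb(-shift)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def format_concentration(c: float, sig: int = 2) -> str:
    """Render a cell concentration the way dilution series are reported, e.g. '7.8e+06'."""
    return f"{round_sig(c, sig):.{max(sig - 1, 0)}e}"
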