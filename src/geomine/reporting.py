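"""Significant-figure rounding and printed-precision interval arithmetic.

Published kinetic constants are printed at limited precision (typically two
significant figures, with trailing zeros non-significant).  To compare a
recomputed quantity against a printed one honestly, each printed number is
treated as an interval: value +/- half a unit in its last significant digit.
"""

from __future__ import annotations

import math

__all__ = ["round_sigfigs", "printed_halfulp", "printed_interval", "intervals_overlap"]


def round_sigfigs(x: float, n: int = 2) -> float:
    """Round ``x`` to ``n`` significant figures (half away from zero)."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (exponent - n + 1)
    return math.copysign(math.floor(abs(x) / factor + 0.5) * factor, x)


def printed_halfulp(text: str) -> float:
    """Half a unit in the last significant digit of a printed decimal.

    Trailing zeros of an integer are treated as non-significant placeholders
    ("32000" -> 500), while digits after a decimal point are significant
    ("0.51" -> 0.005, "10.1" -> 0.05).
    """
    s = text.strip().replace(",", "")
    if not s or s in {"n.d.", "nd", "NA"}:
        raise ValueError(f"not a printed number: {text!r}")
    if "." in s:
        decimals = len(s.split(".", 1)[1])
        return 0.5 * 10.0**-decimals
    digits = s.lstrip("+-")
    trailing_zeros = len(digits) - len(digits.rstrip("0")) if digits.strip("0") else 0
    return 0.5 * 10.0**trailing_zeros


def printed_interval(text: str) -> tuple[float, float]:
    """Interval of real values consistent with a printed decimal."""
    s = text.strip().replace(",", "")
    value = float(s)
    h = printed_halfulp(text)
    return value - h, value + h


def intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]
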