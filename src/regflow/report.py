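"""Small reporting helpers for headline numbers."""

from __future__ import annotations

import math


def percent(part: int | float, whole: int | float, ndigits: int | None = None) -> float:
    """100 * part / whole, optionally rounded to ``ndigits`` decimals."""
    if whole == 0:
        raise ZeroDivisionError("whole is zero")
    value = 100.0 * part / whole
    return round(value, ndigits) if ndigits is not None else value


def round_sig(x: float, n_sig: int) -> float:
    """Round to ``n_sig`` significant figures."""
    if x == 0:
        return 0.0
    if n_sig < 1:
        raise ValueError("n_sig must be >= 1")
    exponent = math.floor(math.log10(abs(x)))
    return round(x, n_sig - 1 - exponent)
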