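"""Presentation rounding helpers.

Headline counts and printed percentages use round-half-away-from-zero,
the convention of the source spreadsheets, not Python's banker's rounding.
"""
from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero."""
    scale = 10.0**ndigits
    scaled = x * scale
    # nudge by one ulp so values that are exact ties after decimal scaling
    # (e.g. 20.35 stored as 20.349999...) still round away from zero
    rounded = math.copysign(math.floor(abs(scaled) + 0.5 + 1e-9), scaled)
    out = rounded / scale
    return out if ndigits > 0 else out


def percent(fraction: float, ndigits: int = 1) -> float:
    """Fraction -> percentage rounded to ``ndigits`` (default one decimal)."""
    return round_half_away(fraction * 100.0, ndigits)
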