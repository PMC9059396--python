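"""Exact half-up rounding helpers.

All reported percentages and group means use round-half-up on exact
rational arithmetic, so .5 ties never depend on binary float artifacts
(e.g. 27/40 -> 67.5% -> 68%).
"""

from __future__ import annotations

import math
from fractions import Fraction
from numbers import Rational


def round_half_up_exact(value: Fraction | Rational, ndigits: int = 0) -> Fraction:
    """Round an exact rational to ``ndigits`` decimals, ties away from floor."""
    scale = Fraction(10) ** ndigits
    scaled = Fraction(value) * scale
    return Fraction(math.floor(scaled + Fraction(1, 2)), 1) / scale


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round a float half-up via its shortest decimal representation.

    Ties round away from zero (-0.5 -> -1.0), matching manual reporting
    conventions for signed percentages.
    """
    frac = Fraction(str(value))
    sign = 1 if frac >= 0 else -1
    rounded = round_half_up_exact(abs(frac), ndigits)
    return float(sign * rounded)


def mean_1dp(values: list[float]) -> float:
    """Arithmetic mean reported at one-decimal precision, half-up."""
    if not values:
        raise ValueError("mean of empty sequence")
    total = sum(Fraction(str(v)) for v in values)
    return float(round_half_up_exact(total / len(values), ndigits=1))
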