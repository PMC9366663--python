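"""Reporting-precision helpers.

Computation always runs at full precision; these helpers apply the survey
report's printing conventions (half-up rounding, two significant figures
for percent ratios, integers for dose indices) only at serialization time.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (school rounding, not banker's)."""
    x = float(x)
    if not math.isfinite(x):
        return x
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 2) -> float:
    """Half-up rounding to ``sig`` significant figures."""
    x = float(x)
    if x == 0 or not math.isfinite(x):
        return x
    ndigits = sig - 1 - math.floor(math.log10(abs(x)))
    return round_half_up(x, ndigits)
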