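"""Report-layer formatting helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero toward +inf at the given precision.

    Matches the presentation convention of printed index tables (1.005 ->
    1.01), unlike banker's rounding.
    """
    if isinstance(x, float) and math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
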