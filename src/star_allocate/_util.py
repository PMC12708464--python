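"""Shared numeric conventions.

Ratios in this package use two distinguished floating-point values:

* ``INFINITE`` (``math.inf``) — a benefit obtained at zero cost (a vertical
  triangle on the frontier, or savings with no implementation cost).
* ``UNDEFINED`` (``math.nan``) — a 0/0 ratio or a quantity whose inputs were
  not estimated.  UNDEFINED values sort after every defined value.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

INFINITE: float = math.inf
UNDEFINED: float = math.nan


def is_undefined(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def is_infinite(x: float) -> bool:
    return isinstance(x, float) and math.isinf(x)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention used for displayed ratios).

    Python's builtin ``round`` is banker's rounding; currency-style tables
    round ties away from zero instead, so 8.705 -> 8.71 and -8.705 -> -8.71.
    NaN/inf pass through unchanged.
    """
    if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
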