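"""Report-time rounding helpers.

All intermediate quantities in the model are carried as reals; rounding
happens once, at report time. Half-up rounding (0.5 rounds away from zero)
is used throughout because that is the convention of the published figures
(e.g. 8.198 -> 8.2 WTE), and Python's built-in banker's rounding would
disagree on exact halves.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimal places, halves away from zero."""
    quantum = Decimal(1).scaleb(-ndigits)
    result = Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(result)


def report_int(value: float) -> int:
    """Half-up rounding to a whole count (persons, appointments)."""
    return int(round_half_up(value, 0))


def two_sig_figs(value: float) -> float:
    """Presentation rounding to two significant figures (53,013 -> 53,000)."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round_half_up(value, ndigits=1 - exponent)
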