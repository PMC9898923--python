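"""Small shared helpers: natural ordering and clinical rounding."""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal

_TOKEN_RE = re.compile(r"(\d+)")


def natural_key(name: object) -> tuple:
    """Sort key that orders embedded integers numerically.

    Needed so that allergen components sort as Der p 1, Der p 2, Der p 5,
    Der p 7, Der p 10, ... rather than lexicographically.
    """
    return tuple(int(tok) if tok.isdigit() else tok for tok in _TOKEN_RE.split(str(name)))


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round to `ndigits` decimals with ties going away from zero.

    Spreadsheet-style commercial rounding; plain round() uses banker's
    rounding which disagrees on exact halves (e.g. 0.125 -> 0.12).
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
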