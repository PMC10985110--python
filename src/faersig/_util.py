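"""Small shared helpers: half-up rounding, ID ordering, compact date parsing."""

from __future__ import annotations

import datetime as _dt
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed tables conventionally do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def exact_percent(count: int, total: int, ndigits: int = 2) -> float:
    """100*count/total rounded half-up, computed exactly (no float division)."""
    if total <= 0:
        raise ValueError("percentage denominator must be positive")
    frac = Fraction(100 * count, total)
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(frac.numerator) / Decimal(frac.denominator)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def id_sort_key(identifier: str):
    """Numeric-aware ordering for case/report IDs.

    All-digit IDs compare by integer value; anything else compares
    lexicographically after every numeric ID.
    """
    s = identifier.strip()
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


def parse_compact_date(raw: str, allow_partial: bool = False) -> _dt.date | None:
    """Parse a YYYYMMDD date string; return None for empty input.

    With ``allow_partial``, 4-digit (YYYY) and 6-digit (YYYYMM) values are
    padded to the first day of the period. Raises ValueError for anything
    that is not a valid calendar date of the accepted widths.
    """
    s = raw.strip()
    if not s:
        return None
    if not s.isdigit():
        raise ValueError(f"invalid date {raw!r}")
    if len(s) == 8:
        return _dt.datetime.strptime(s, "%Y%m%d").date()
    if allow_partial and len(s) == 4:
        return _dt.date(int(s), 1, 1)
    if allow_partial and len(s) == 6:
        return _dt.datetime.strptime(s + "01", "%Y%m%d").date()
    raise ValueError(f"invalid date {raw!r}")


def format_compact_date(d: _dt.date | None) -> str:
    return "" if d is None else d.strftime("%Y%m%d")
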