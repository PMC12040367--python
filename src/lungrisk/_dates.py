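"""Calendar-month arithmetic with day clamping.

All window logic in this package shifts dates by whole calendar months and
clamps the day-of-month to the end of the target month (Mar 31 - 1 month ->
Feb 28/29). Clamping keeps the shift total-order preserving and unambiguous.
"""

from __future__ import annotations

import calendar
import datetime as dt


def add_months(d: dt.date, months: int) -> dt.date:
    """Shift ``d`` by ``months`` calendar months, clamping the day."""
    y, m = divmod(d.month - 1 + months, 12)
    year, month = d.year + y, m + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def parse_year_month(ym: str) -> tuple[int, int]:
    """Parse ``YYYY-MM``; raises ValueError on malformed input."""
    parts = ym.split("-")
    if len(parts) != 2:
        raise ValueError(f"malformed year-month: {ym!r}")
    year, month = int(parts[0]), int(parts[1])
    if not 1 <= month <= 12:
        raise ValueError(f"malformed year-month: {ym!r}")
    return year, month


def mid_month(ym: str) -> dt.date:
    """Day 15 of a ``YYYY-MM`` month — the mid-month estimate of an
    event whose exact day is unknown (e.g. a registry diagnosis month)."""
    year, month = parse_year_month(ym)
    return dt.date(year, month, 15)


def months_between(earlier: dt.date, later: dt.date) -> int:
    """Whole calendar months from ``earlier`` to ``later`` (floor)."""
    m = (later.year - earlier.year) * 12 + (later.month - earlier.month)
    if later.day < earlier.day:
        m -= 1
    return m
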