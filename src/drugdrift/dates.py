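"""Calendar arithmetic with end-of-month clamping.

Snapshot schedules, publication lags and release grids all step in whole
months.  The convention throughout is that adding months to a month-end
date yields the target month's end (1965-11-30 + 2 months = 1966-01-31),
and adding months to any other day clamps the day into the target month
(2000-01-31 + 1 month = 2000-02-29).
"""

from __future__ import annotations

import calendar
import datetime as _dt

__all__ = ["add_months", "days_in_month", "is_month_end", "months_between", "parse_date"]


def days_in_month(year: int, month: int) -> int:
    return calendar.monthrange(year, month)[1]


def is_month_end(d: _dt.date) -> bool:
    return d.day == days_in_month(d.year, d.month)


def add_months(d: _dt.date, n: int) -> _dt.date:
    """Shift ``d`` by ``n`` whole months (n may be negative).

    Month-end dates map to month-end dates; otherwise the day of month is
    preserved, clamped to the target month's length.
    """
    month_index = d.year * 12 + (d.month - 1) + n
    year, month = divmod(month_index, 12)
    month += 1
    dim = days_in_month(year, month)
    day = dim if is_month_end(d) else min(d.day, dim)
    return _dt.date(year, month, day)


def months_between(start: _dt.date, end: _dt.date) -> int:
    """Whole months from ``start`` to ``end`` counted on the year/month grid."""
    return (end.year - start.year) * 12 + (end.month - start.month)


def parse_date(value: str | _dt.date) -> _dt.date:
    """Accept ``datetime.date`` or ISO ``YYYY-MM-DD`` strings.

    As a convenience, an out-of-range day-of-month (e.g. "31 November") is
    clamped to the month's last day, matching the month-end convention used
    by the snapshot schedule.
    """
    if isinstance(value, _dt.date):
        return value
    year_s, month_s, day_s = value.strip().split("-")
    year, month, day = int(year_s), int(month_s), int(day_s)
    day = min(day, days_in_month(year, month))
    return _dt.date(year, month, day)
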