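"""Calendar-month arithmetic shared by the price panel and cost engine.

Months are (year, month) integer pairs; windows are closed intervals.
"""

from __future__ import annotations

import calendar

Month = tuple[int, int]


def month_index(month: Month) -> int:
    """Map (year, month) to a consecutive integer (month differences in months)."""
    y, m = month
    if not 1 <= m <= 12:
        raise ValueError(f"month out of range: {month}")
    return y * 12 + (m - 1)


def from_index(idx: int) -> Month:
    return idx // 12, idx % 12 + 1


def month_range(start: Month, end: Month) -> list[Month]:
    """All months from start to end, both inclusive."""
    a, b = month_index(start), month_index(end)
    if a > b:
        raise ValueError(f"window start {start} after end {end}")
    return [from_index(i) for i in range(a, b + 1)]


def n_months(start: Month, end: Month) -> int:
    return month_index(end) - month_index(start) + 1


def days_in_month(month: Month, policy: str = "calendar") -> int:
    """Days of a month under a policy: 'calendar' (true length) or 'fixed30'."""
    if policy == "calendar":
        return calendar.monthrange(month[0], month[1])[1]
    if policy == "fixed30":
        return 30
    raise ValueError(f"unknown days policy: {policy!r}")


def parse_month(text: str) -> Month:
    """Parse 'YYYY-MM' into a (year, month) pair."""
    y, m = text.split("-")
    return int(y), int(m)
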