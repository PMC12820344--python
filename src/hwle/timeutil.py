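"""Month-resolution date arithmetic.

All survey dates are carried at month resolution as ``YYYY-MM`` strings (the
source data report month and year only).  For age arithmetic a date is
anchored mid-month (day 15) and ages are exact fractional years,
days / 365.25, from birth date to observation date.
"""

from __future__ import annotations

import datetime

DAYS_PER_YEAR = 365.25


def month_index(date: str | tuple[int, int]) -> int:
    """Months since year 0 for a ``YYYY-MM`` string or ``(year, month)`` pair."""
    if isinstance(date, str):
        y, m = date.split("-")
        year, month = int(y), int(m)
    else:
        year, month = date
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range in {date!r}")
    return year * 12 + (month - 1)


def month_str(idx: int) -> str:
    """Inverse of :func:`month_index`."""
    return f"{idx // 12:04d}-{idx % 12 + 1:02d}"


def _mid_month(idx: int) -> datetime.date:
    return datetime.date(idx // 12, idx % 12 + 1, 15)


def age_at(birth: str | int, observation: str | int) -> float:
    """Age in exact fractional years at an observation date.

    Both dates are taken at mid-month; the difference in days is divided by
    365.25.
    """
    b = birth if isinstance(birth, int) else month_index(birth)
    o = observation if isinstance(observation, int) else month_index(observation)
    if o < b:
        raise ValueError("observation precedes birth")
    return (_mid_month(o) - _mid_month(b)).days / DAYS_PER_YEAR
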