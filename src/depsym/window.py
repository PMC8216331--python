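"""Study window: calendar dates, ISO weeks and contact-ban periods.

The study window covers ISO calendar weeks 1-31 of 2020 (January 1 to
July 30), split into three periods around the first German social-contact
ban: *before* (weeks 1-11), *during* (weeks 12-18) and *after* (weeks
19-31).  Edge weeks may be partial: ISO week 1 of 2020 starts on
December 30, 2019, so only five of its days fall inside the window.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

PERIOD_BOUNDS_DEFAULT: tuple[int, int] = (11, 18)


def label_period(week: int, bounds: tuple[int, int] = PERIOD_BOUNDS_DEFAULT,
                 week_range: tuple[int, int] = (1, 31)) -> str:
    """Assign a calendar week to the before/during/after contact-ban period.

    ``bounds = (b1, b2)`` puts weeks ``<= b1`` before, ``b1 < w <= b2``
    during, and ``> b2`` after the ban.
    """
    lo, hi = week_range
    if not lo <= week <= hi:
        raise ValueError(f"week {week} outside study window {lo}..{hi}")
    b1, b2 = bounds
    if not lo <= b1 < b2 <= hi:
        raise ValueError(f"period bounds {bounds} not strictly increasing inside {week_range}")
    if week <= b1:
        return "before"
    if week <= b2:
        return "during"
    return "after"


@dataclass(frozen=True)
class StudyWindow:
    """Date range of the analysis with ISO-week bookkeeping.

    ISO-8601 week numbers are used throughout ("calendar week" in the German
    convention).  The window must not straddle an ISO year boundary in its
    week numbering; the default (2020-01-01 .. 2020-07-30) does not.
    """

    start: dt.date = dt.date(2020, 1, 1)
    end: dt.date = dt.date(2020, 7, 30)
    period_bounds: tuple[int, int] = PERIOD_BOUNDS_DEFAULT
    _week_days: dict[int, list[dt.date]] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("window end precedes start")
        days: dict[int, list[dt.date]] = {}
        years = set()
        d = self.start
        while d <= self.end:
            iso = d.isocalendar()
            years.add(iso[0])
            days.setdefault(iso[1], []).append(d)
            d += dt.timedelta(days=1)
        if len(years) > 1:
            raise ValueError(f"window spans multiple ISO years {sorted(years)}")
        object.__setattr__(self, "_week_days", days)
        b1, b2 = self.period_bounds
        lo, hi = self.week_range
        if not lo <= b1 < b2 <= hi:
            raise ValueError(f"period bounds {self.period_bounds} outside week range {lo}..{hi}")

    @property
    def iso_year(self) -> int:
        return self.start.isocalendar()[0]

    @property
    def weeks(self) -> list[int]:
        return sorted(self._week_days)

    @property
    def week_range(self) -> tuple[int, int]:
        w = self.weeks
        return (w[0], w[-1])

    def week_dates(self, week: int) -> list[dt.date]:
        """Dates of `week` that fall inside the window."""
        return list(self._week_days[week])

    def days_in_week(self, week: int) -> int:
        return len(self._week_days[week])

    def is_partial(self, week: int) -> bool:
        return self.days_in_week(week) < 7

    def contains(self, date: dt.date) -> bool:
        return self.start <= date <= self.end

    def week_of(self, date: dt.date) -> int:
        if not self.contains(date):
            raise ValueError(f"{date} outside window")
        return date.isocalendar()[1]

    def period_of_week(self, week: int) -> str:
        return label_period(week, self.period_bounds, self.week_range)


DEFAULT_WINDOW = StudyWindow()
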