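"""Day-indexed hospital calendars.

The pipeline works on integer day indices (0-based day of the study year)
rather than datestamps.  A :class:`Calendar` pins each day index to a weekday
(0 = Monday ... 6 = Sunday) and flags hospital holidays, which are the only
calendar features the forecasting models consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Calendar", "generate_calendar", "default_holidays"]


@dataclass(frozen=True)
class Calendar:
    """A contiguous run of ``n_days`` days with a consistent weekly cycle.

    Parameters
    ----------
    n_days:
        Number of days covered, day indices ``0 .. n_days - 1``.
    day0_weekday:
        Weekday of day 0 (0 = Monday ... 6 = Sunday).
    holidays:
        Day indices observed as hospital holidays.
    """

    n_days: int
    day0_weekday: int = 0
    holidays: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0 <= self.day0_weekday <= 6:
            raise ValueError("day0_weekday must be in 0..6")
        object.__setattr__(self, "holidays", frozenset(int(h) for h in self.holidays))
        bad = [h for h in self.holidays if not 0 <= h < self.n_days]
        if bad:
            raise ValueError(f"holiday day indices out of range: {sorted(bad)}")

    def weekday_of(self, day: int) -> int:
        return (self.day0_weekday + day) % 7

    def is_holiday(self, day: int) -> bool:
        return day in self.holidays

    @property
    def weekdays(self) -> np.ndarray:
        """Vector of weekdays, one entry per day index."""
        return (self.day0_weekday + np.arange(self.n_days)) % 7

    @property
    def is_weekend(self) -> np.ndarray:
        return self.weekdays >= 5

    @property
    def holiday_indicator(self) -> np.ndarray:
        """0/1 vector over day indices; holidays are calendar-known in advance."""
        ind = np.zeros(self.n_days, dtype=int)
        if self.holidays:
            ind[sorted(self.holidays)] = 1
        return ind

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day_index": np.arange(self.n_days),
                "weekday": self.weekdays,
                "is_holiday": self.holiday_indicator.astype(bool),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Calendar":
        frame = frame.sort_values("day_index").reset_index(drop=True)
        n_days = len(frame)
        day0 = int(frame.loc[0, "weekday"])
        holidays = frozenset(frame.loc[frame["is_holiday"].astype(bool), "day_index"].astype(int))
        return cls(n_days=n_days, day0_weekday=day0, holidays=holidays)


def generate_calendar(n_days: int, day0_weekday: int, holidays: set[int] | frozenset[int]) -> Calendar:
    """Build a calendar; validates that holidays fall inside ``[0, n_days)``."""
    return Calendar(n_days=n_days, day0_weekday=day0_weekday, holidays=frozenset(holidays))


def default_holidays(n_days: int = 365, day0_weekday: int = 4) -> frozenset[int]:
    """A typical US hospital holiday calendar for a July-anchored study year.

    Day 0 is July 1 (a Friday when ``day0_weekday=4``); the set covers
    Independence Day, Labor Day, Thanksgiving (and the day after), Christmas,
    New Year's Day, MLK Day, Presidents' Day, and Memorial Day.
    """
    candidates = [3, 66, 146, 147, 177, 184, 200, 235, 333]
    return frozenset(d for d in candidates if d < n_days)
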