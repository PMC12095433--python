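"""Day-indexed numeric series on a hospital calendar."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calendars import Calendar

__all__ = ["DailySeries"]


@dataclass(frozen=True)
class DailySeries:
    """One number per calendar day (counts, census, or a 0/1 indicator)."""

    calendar: Calendar
    values: np.ndarray
    name: str = "series"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if len(values) != self.calendar.n_days:
            raise ValueError(
                f"series length {len(values)} does not match calendar ({self.calendar.n_days} days)"
            )
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day_index": np.arange(len(self.values)), "value": self.values})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, calendar: Calendar, name: str = "series") -> "DailySeries":
        frame = pd.read_csv(path).sort_values("day_index")
        return cls(calendar=calendar, values=frame["value"].to_numpy(), name=name)
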