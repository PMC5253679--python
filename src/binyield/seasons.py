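"""Growing-season windows and harvest-year date arithmetic."""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

__all__ = ["GrowingSeason", "default_season", "DEFAULT_SEASONS"]


@dataclass(frozen=True)
class GrowingSeason:
    """A fixed calendar growing season, assigned to its harvest year.

    A season that spans the calendar-year boundary (winter wheat) starts in
    the year *before* the harvest year: e.g. the 1995 wheat season runs
    Oct 15 1994 - Jul 15 1995.
    """

    crop: str
    start_month: int
    start_day: int
    end_month: int
    end_day: int
    spans_calendar_year: bool = False

    def window(self, harvest_year: int) -> tuple[date, date]:
        start_year = harvest_year - 1 if self.spans_calendar_year else harvest_year
        return (
            date(start_year, self.start_month, self.start_day),
            date(harvest_year, self.end_month, self.end_day),
        )

    def dates(self, harvest_year: int) -> pd.DatetimeIndex:
        """All calendar days of the season, endpoints inclusive (leap days kept)."""
        start, end = self.window(harvest_year)
        return pd.date_range(start, end, freq="D")

    def length(self, harvest_year: int) -> int:
        return len(self.dates(harvest_year))


DEFAULT_SEASONS: dict[str, GrowingSeason] = {
    "maize": GrowingSeason("maize", 3, 1, 8, 31),
    "soybean": GrowingSeason("soybean", 3, 1, 8, 31),
    "wheat": GrowingSeason("wheat", 10, 15, 7, 15, spans_calendar_year=True),
}


def default_season(crop: str) -> GrowingSeason:
    """Fixed default season: Mar 01 - Aug 31 (maize, soybean), Oct 15 - Jul 15 (wheat)."""
    try:
        return DEFAULT_SEASONS[crop]
    except KeyError:
        raise KeyError(
            f"no default season for crop {crop!r}; known: {sorted(DEFAULT_SEASONS)}"
        ) from None
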