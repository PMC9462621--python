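"""Monthly count series: the universal forecasting input.

A :class:`MonthlySeries` is an ordered, gap-free sequence of calendar months
with a non-negative integer count per month.  Months are represented as
pandas ``Period`` objects with monthly frequency; a referral belongs to the
month containing its date (day-of-month is discarded at aggregation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError


@dataclass(frozen=True)
class MonthlySeries:
    """Gap-free monthly counts.

    Parameters
    ----------
    months : pd.PeriodIndex
        Strictly increasing, consecutive calendar months (freq ``M``).
    counts : np.ndarray
        Non-negative integer counts, one per month.
    """

    months: pd.PeriodIndex
    counts: np.ndarray = field()

    def __post_init__(self):
        months = pd.PeriodIndex(self.months, freq="M")
        counts = np.asarray(self.counts)
        if months.size != counts.size:
            raise InvalidArgumentError(
                f"months ({months.size}) and counts ({counts.size}) differ in length"
            )
        if months.size == 0:
            raise InvalidArgumentError("series must contain at least one month")
        if not np.issubdtype(counts.dtype, np.number):
            raise InvalidArgumentError("counts must be numeric")
        if np.any(counts < 0):
            raise InvalidArgumentError("counts must be non-negative")
        if months.size > 1:
            steps = np.diff(months.asi8)
            if np.any(steps != 1):
                raise InvalidArgumentError(
                    "months must be consecutive with no gaps; found a jump of "
                    f"{int(steps.max())} months"
                )
        object.__setattr__(self, "months", months)
        # referral counts are integers; real-valued series (decomposition
        # components, noiseless test signals) are carried as floats
        if np.allclose(counts, np.round(counts.astype(float))):
            counts = np.round(counts.astype(float)).astype(np.int64)
        else:
            counts = counts.astype(float)
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_start(cls, start: str, counts) -> "MonthlySeries":
        """Build a series from a start month (``'YYYY-MM'``) and counts."""
        counts = np.asarray(counts)
        months = pd.period_range(start=start, periods=counts.size, freq="M")
        return cls(months, counts)

    @property
    def values(self) -> np.ndarray:
        """Counts as floats (for smoothing and model fitting)."""
        return self.counts.astype(float)

    def __len__(self) -> int:
        return len(self.months)

    def slice(self, start: int, stop: int) -> "MonthlySeries":
        """Positional sub-series ``[start, stop)``."""
        if not 0 <= start < stop <= len(self):
            raise InvalidArgumentError(f"invalid slice [{start}, {stop}) of length {len(self)}")
        return MonthlySeries(self.months[start:stop], self.counts[start:stop])

    def window(self, start: str, end: str) -> "MonthlySeries":
        """Sub-series between two months inclusive (``'YYYY-MM'`` strings)."""
        lo, hi = pd.Period(start, freq="M"), pd.Period(end, freq="M")
        mask = (self.months >= lo) & (self.months <= hi)
        if not mask.any():
            raise InvalidArgumentError(f"window {start}..{end} is outside the series span")
        return MonthlySeries(self.months[mask], self.counts[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.months.astype(str), "count": self.counts})

    def future_months(self, horizon: int) -> pd.PeriodIndex:
        """The ``horizon`` months immediately following the series."""
        return pd.period_range(self.months[-1] + 1, periods=horizon, freq="M")


@dataclass(frozen=True)
class Forecast:
    """Point forecasts with symmetric interval bounds at a stated level."""

    horizon: int
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def __post_init__(self):
        point = np.asarray(self.point, dtype=float)
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if self.horizon <= 0:
            raise InvalidArgumentError("horizon must be positive")
        if not (point.size == lower.size == upper.size == self.horizon):
            raise InvalidArgumentError("point/lower/upper must all have length horizon")
        if not 0 < self.level < 1:
            raise InvalidArgumentError("level must lie in (0, 1)")
        # allow tiny numerical slack before declaring the invariant broken
        if np.any(lower > point + 1e-9) or np.any(point > upper + 1e-9):
            raise InvalidArgumentError("interval bounds must bracket the point forecast")
        object.__setattr__(self, "point", point)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
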