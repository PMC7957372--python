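"""Core domain types for population-scale CGM analysis.

A cohort is a set of users, each with a stream of ~5-minute sensor glucose
readings and a metadata record (geography, zip-level median income, upload
tenure).  Analyses are carried out over named observation windows — closed
date intervals that partition exactly into 7-day weeks.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

#: Reportable sensor range, mg/dL.  Values outside are dropped at ingest.
GLUCOSE_MIN = 40
GLUCOSE_MAX = 400

#: Sensor cadence: one reading every 5 minutes.
SLOT_SECONDS = 300
SLOTS_PER_DAY = 86400 // SLOT_SECONDS  # 288

UNASSIGNED_REGION = "unassigned"


class GlucoseReading(NamedTuple):
    """A single timestamped sensor glucose value (mg/dL)."""

    timestamp: dt.datetime
    glucose: int


def months_between(first: dt.date, last: dt.date) -> int:
    """Whole calendar months between two dates (floor), >= 0 for last >= first."""
    if last < first:
        raise ValueError(f"last date {last} precedes first date {first}")
    months = (last.year - first.year) * 12 + (last.month - first.month)
    if last.day < first.day:
        months -= 1
    return months


@dataclass
class GlucoseStream:
    """One user's glucose readings, held as parallel numpy arrays.

    ``times`` is a ``datetime64[s]`` array in the analysis reference timezone
    (naive; UTC by default at ingest) and must be strictly increasing.
    """

    user_id: str
    times: np.ndarray
    glucose: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.glucose = np.asarray(self.glucose)
        if self.times.shape != self.glucose.shape:
            raise ValueError("times and glucose must have equal length")
        if self.times.size > 1 and not (np.diff(self.times).astype(np.int64) > 0).all():
            raise ValueError(f"stream for {self.user_id!r} not strictly increasing in time")

    def __len__(self) -> int:
        return int(self.times.size)

    def __iter__(self) -> Iterator[GlucoseReading]:
        for t, g in zip(self.times.tolist(), self.glucose.tolist()):
            yield GlucoseReading(t, int(g))

    def restrict(self, window: "ObservationWindow") -> "GlucoseStream":
        """Readings falling inside the window's closed date interval."""
        lo = np.datetime64(window.start_date, "s")
        hi = np.datetime64(window.end_date + dt.timedelta(days=1), "s")
        i = np.searchsorted(self.times, lo, side="left")
        j = np.searchsorted(self.times, hi, side="left")
        return GlucoseStream(self.user_id, self.times[i:j], self.glucose[i:j])


@dataclass(frozen=True)
class ObservationWindow:
    """A named closed date interval spanning a whole number of weeks."""

    label: str
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError(f"window {self.label!r}: end before start")
        if self.n_days % 7 != 0:
            raise ValueError(
                f"window {self.label!r} spans {self.n_days} days; must be a multiple of 7"
            )

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    @property
    def n_weeks(self) -> int:
        return self.n_days // 7

    def days(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=i) for i in range(self.n_days)]

    def weeks(self) -> list["ObservationWindow"]:
        """Consecutive 7-day sub-windows anchored at the start date."""
        out = []
        for k in range(self.n_weeks):
            s = self.start_date + dt.timedelta(days=7 * k)
            out.append(ObservationWindow(f"{self.label}/week{k + 1}", s, s + dt.timedelta(days=6)))
        return out

    @classmethod
    def parse(cls, label: str, text: str) -> "ObservationWindow":
        """Parse ``YYYY-MM-DD:YYYY-MM-DD`` into a window."""
        a, _, b = text.partition(":")
        return cls(label, dt.date.fromisoformat(a), dt.date.fromisoformat(b))


# The study's canonical windows: 8 weeks ending 2020-03-01 (prepandemic),
# 8 weeks ending 2020-06-14 (intrapandemic), and the relaxed-density late
# window of 8 weeks ending 2020-08-09.
PRE_WINDOW = ObservationWindow("prepandemic", dt.date(2020, 1, 6), dt.date(2020, 3, 1))
POST_WINDOW = ObservationWindow("intrapandemic", dt.date(2020, 4, 20), dt.date(2020, 6, 14))
LATE_WINDOW = ObservationWindow("late", dt.date(2020, 6, 15), dt.date(2020, 8, 9))


@dataclass
class UserRecord:
    """Geographic, economic and tenure attributes of one uploader."""

    user_id: str
    zip: str
    county_fips: str
    state: str
    median_income: float
    first_upload: dt.date
    last_upload: dt.date
    mobile_app: bool
    region: str = UNASSIGNED_REGION

    @property
    def tenure_months(self) -> int:
        """Whole months between first and most recent upload."""
        return months_between(self.first_upload, self.last_upload)


@dataclass(frozen=True)
class CountyBurdenRow:
    """One row of a cumulative county COVID burden table."""

    date: dt.date
    county: str
    state: str
    fips: str
    cases: int
    deaths: int

    def __post_init__(self) -> None:
        if not (self.cases >= self.deaths >= 0):
            raise ValueError(f"fips {self.fips}: need cases >= deaths >= 0")
        if not (len(self.fips) == 5 and self.fips.isdigit()):
            raise ValueError(f"malformed fips {self.fips!r}")
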