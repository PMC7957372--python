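"""Cohort inclusion criteria and per-window data-density rules.

A user enters the paired analysis only if they (1) started uploading on or
before the enrollment cutoff (2020-01-01), (2) used the mobile app, (3)
uploaded at least one value in every month of January–June 2020, and (4)
satisfied the data-density rule — at least 200 readings per day on at least
4 days per week — in both observation windows.  The density rule can be
relaxed (``enabled=False``) as for the late-summer window, or evaluated per
whole window instead of per week.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .data_model import GlucoseStream, ObservationWindow, UserRecord

#: All failure reasons an InclusionReport may carry.
FAILURE_REASONS = ("late_start", "not_mobile", "missing_month", "density_pre", "density_post")

START_CUTOFF = dt.date(2020, 1, 1)

#: (year, month) pairs of the default monthly-presence requirement.
DEFAULT_MONTHS: tuple[tuple[int, int], ...] = tuple((2020, m) for m in range(1, 7))


@dataclass(frozen=True)
class DensityRule:
    """Data-density requirement applied inside each observation window."""

    min_readings_per_day: int = 200
    min_days_per_week: int = 4
    enabled: bool = True
    scope: Literal["per_week", "per_window"] = "per_week"


@dataclass
class InclusionReport:
    user_id: str
    passed: bool
    failure_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.passed == (not self.failure_reasons)


def daily_counts(stream: GlucoseStream | None, window: ObservationWindow) -> dict[dt.date, int]:
    """Reading count for every calendar day of the window (0 for absent days)."""
    counts = np.zeros(window.n_days, dtype=np.int64)
    if stream is not None and len(stream):
        sub = stream.restrict(window)
        if len(sub):
            day_idx = (
                sub.times.astype("datetime64[D]") - np.datetime64(window.start_date, "D")
            ).astype(np.int64)
            counts = np.bincount(day_idx, minlength=window.n_days)
    return dict(zip(window.days(), counts.tolist()))


def passes_density(
    stream: GlucoseStream | None,
    window: ObservationWindow,
    rule: DensityRule = DensityRule(),
) -> bool:
    """Whether a stream meets the density rule over a window.

    ``per_week`` scope (default) requires every 7-day week of the window to
    contain at least ``min_days_per_week`` qualifying days; ``per_window``
    requires the same number of qualifying days on average, i.e.
    ``min_days_per_week * n_weeks`` over the whole window.  A disabled rule
    always passes.
    """
    if not rule.enabled:
        return True
    counts = np.fromiter(daily_counts(stream, window).values(), dtype=np.int64)
    qualifying = counts >= rule.min_readings_per_day
    if rule.scope == "per_window":
        return int(qualifying.sum()) >= rule.min_days_per_week * window.n_weeks
    per_week = qualifying.reshape(window.n_weeks, 7).sum(axis=1)
    return bool((per_week >= rule.min_days_per_week).all())


def monthly_presence(
    stream: GlucoseStream | None,
    months: Sequence[tuple[int, int]] = DEFAULT_MONTHS,
) -> bool:
    """True iff the stream has >= 1 reading in every listed calendar month."""
    if not months:
        return True
    if stream is None or not len(stream):
        return False
    ym = stream.times.astype("datetime64[M]")
    present = {(int(str(m)[:4]), int(str(m)[5:7])) for m in np.unique(ym)}
    return all(tuple(m) in present for m in months)


def filter_cohort(
    users: Sequence[UserRecord],
    streams: Mapping[str, GlucoseStream],
    pre_window: ObservationWindow,
    post_window: ObservationWindow,
    rule: DensityRule = DensityRule(),
    start_cutoff: dt.date = START_CUTOFF,
    required_months: Sequence[tuple[int, int]] = DEFAULT_MONTHS,
) -> tuple[list[UserRecord], list[InclusionReport]]:
    """Apply the full inclusion criteria; report every user.

    Returns the included users (in input order) and one
    :class:`InclusionReport` per input user.  A user without a stream fails
    the monthly-presence and both density criteria.
    """
    included: list[UserRecord] = []
    reports: list[InclusionReport] = []
    for user in users:
        stream = streams.get(user.user_id)
        reasons = []
        if user.first_upload > start_cutoff:
            reasons.append("late_start")
        if not user.mobile_app:
            reasons.append("not_mobile")
        if not monthly_presence(stream, required_months):
            reasons.append("missing_month")
        if not passes_density(stream, pre_window, rule):
            reasons.append("density_pre")
        if not passes_density(stream, post_window, rule):
            reasons.append("density_post")
        reports.append(InclusionReport(user.user_id, not reasons, reasons))
        if not reasons:
            included.append(user)
    return included, reports
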