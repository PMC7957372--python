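"""Paired pre/post cohort comparison.

Each included user contributes one pre-window and one post-window metrics
row; the comparison summarizes the paired TIR change distribution, classifies
users by clinically meaningful change (|ΔTIR| >= 5 percentage points), runs
the dependent-samples t-test on the TIR deltas, and produces TIR histograms
and weekly mean ± SEM trajectories.
"""
from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GlucoseStream, ObservationWindow, UserRecord
from .metrics import DEFAULT_THRESHOLDS, MetricThresholds, UndefinedMetricError, compute_window_metrics

logger = logging.getLogger(__name__)

MEANINGFUL_TIR_CHANGE = 5.0

CATEGORY_INCREASE = "meaningful_increase"
CATEGORY_DECREASE = "meaningful_decrease"
CATEGORY_INTERMEDIATE = "intermediate"

TRAJECTORY_METRICS = ("tir", "mean_glucose", "cv", "tar250", "tbr54")


def classify_change(delta_tir: float, threshold: float = MEANINGFUL_TIR_CHANGE) -> str:
    """Category of a TIR change; thresholds inclusive ("at least 5 points")."""
    if delta_tir >= threshold:
        return CATEGORY_INCREASE
    if delta_tir <= -threshold:
        return CATEGORY_DECREASE
    return CATEGORY_INTERMEDIATE


def paired_t_test(deltas: np.ndarray) -> tuple[float, int, float]:
    """Dependent-samples t-test on paired differences.

    Returns ``(t, df, p)`` with ``t = mean / (SD/sqrt(n))``, ``df = n - 1``
    and a two-sided p-value from the t distribution.
    """
    deltas = np.asarray(deltas, dtype=float)
    n = deltas.size
    if n < 2:
        raise ValueError("paired t-test requires at least two pairs")
    sd = deltas.std(ddof=1)
    if sd == 0:
        raise ValueError("paired t-test degenerate: zero variance in differences")
    t = float(deltas.mean() / (sd / math.sqrt(n)))
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, p


def as_pct(count: int, total: int, ndigits: int = 1) -> float:
    """A count as a percentage of a total, at reporting precision."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


@dataclass
class CohortComparison:
    """Paired pre/post summary over the common user set."""

    n: int
    tir_pre_mean: float
    tir_pre_sd: float
    tir_post_mean: float
    tir_post_sd: float
    mean_glucose_pre_mean: float
    mean_glucose_pre_sd: float
    mean_glucose_post_mean: float
    mean_glucose_post_sd: float
    gmi_pre_mean: float
    gmi_pre_sd: float
    gmi_post_mean: float
    gmi_post_sd: float
    delta_tir_mean: float
    delta_tir_sd: float
    delta_mean_glucose_mean: float
    fraction_improved: float
    fraction_meaningful_increase: float
    fraction_meaningful_decrease: float
    tir_goal_pre: float
    tir_goal_post: float
    tar250_goal_pre: float
    tar250_goal_post: float
    t_statistic: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return asdict(self)


def paired_changes(
    pre: pd.DataFrame, post: pd.DataFrame, threshold: float = MEANINGFUL_TIR_CHANGE
) -> pd.DataFrame:
    """Per-user paired deltas and change categories.

    ``pre`` and ``post`` are metrics tables indexed by user_id.  Users missing
    either window are dropped (count logged).
    """
    common = pre.index.intersection(post.index)
    dropped = len(pre.index.union(post.index)) - len(common)
    if dropped:
        logger.info("paired comparison: %d users missing one window, excluded", dropped)
    if len(common) == 0:
        raise ValueError("no users present in both windows")
    delta_tir = post.loc[common, "tir"] - pre.loc[common, "tir"]
    delta_mg = post.loc[common, "mean_glucose"] - pre.loc[common, "mean_glucose"]
    return pd.DataFrame({
        "delta_tir": delta_tir,
        "delta_mean_glucose": delta_mg,
        "category": [classify_change(d, threshold) for d in delta_tir],
    }, index=common)


def summarize_comparison(
    pre: pd.DataFrame, post: pd.DataFrame, threshold: float = MEANINGFUL_TIR_CHANGE
) -> CohortComparison:
    """Full paired summary; see :class:`CohortComparison` for the fields."""
    changes = paired_changes(pre, post, threshold)
    common = changes.index
    p, q = pre.loc[common], post.loc[common]
    n = len(common)
    d = changes["delta_tir"].to_numpy()
    try:
        t, df, pval = paired_t_test(d)
    except ValueError:
        # degenerate change distribution (e.g. post identical to pre)
        t, df, pval = math.nan, n - 1, math.nan
        logger.warning("paired t-test degenerate (zero-variance deltas); reported as NaN")
    cat = changes["category"]

    def _ms(col: pd.Series) -> tuple[float, float]:
        return float(col.mean()), float(col.std(ddof=1)) if n > 1 else math.nan

    tir_pre = _ms(p["tir"]); tir_post = _ms(q["tir"])
    mg_pre = _ms(p["mean_glucose"]); mg_post = _ms(q["mean_glucose"])
    gmi_pre = _ms(p["gmi"]); gmi_post = _ms(q["gmi"])
    return CohortComparison(
        n=n,
        tir_pre_mean=tir_pre[0], tir_pre_sd=tir_pre[1],
        tir_post_mean=tir_post[0], tir_post_sd=tir_post[1],
        mean_glucose_pre_mean=mg_pre[0], mean_glucose_pre_sd=mg_pre[1],
        mean_glucose_post_mean=mg_post[0], mean_glucose_post_sd=mg_post[1],
        gmi_pre_mean=gmi_pre[0], gmi_pre_sd=gmi_pre[1],
        gmi_post_mean=gmi_post[0], gmi_post_sd=gmi_post[1],
        delta_tir_mean=float(d.mean()),
        delta_tir_sd=float(d.std(ddof=1)) if n > 1 else math.nan,
        delta_mean_glucose_mean=float(changes["delta_mean_glucose"].mean()),
        fraction_improved=float((d > 0).mean()),
        fraction_meaningful_increase=float((cat == CATEGORY_INCREASE).mean()),
        fraction_meaningful_decrease=float((cat == CATEGORY_DECREASE).mean()),
        tir_goal_pre=float(p["meets_tir_goal"].mean()),
        tir_goal_post=float(q["meets_tir_goal"].mean()),
        tar250_goal_pre=float(p["meets_tar250_goal"].mean()),
        tar250_goal_post=float(q["meets_tar250_goal"].mean()),
        t_statistic=t, df=df, p_value=pval,
    )


def tir_histogram(tir_values: Sequence[float], bin_width: float = 2.5) -> pd.DataFrame:
    """Counts of users per TIR bin over [0, 100].

    Bins are left-closed right-open except the last, which is closed so a TIR
    of exactly 100 is counted.  Counts always sum to ``len(tir_values)``.
    """
    if not 0 < bin_width <= 100:
        raise ValueError("bin width must lie in (0, 100]")
    n_bins = math.ceil(100 / bin_width)
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 100.0)
    counts, _ = np.histogram(np.asarray(tir_values, dtype=float), bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


@dataclass(frozen=True)
class TrajectoryPoint:
    group: str
    week_start: dt.date
    n: int
    mean: float
    sem: float


def weekly_trajectory(
    streams: Mapping[str, GlucoseStream],
    users: Sequence[UserRecord],
    metric: str,
    start_date: dt.date,
    end_date: dt.date,
    group_by: str | None = None,
    thresholds: MetricThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Weekly mean ± SEM of a metric, per group of users.

    The metric is computed per user per 7-day week (weeks anchored at
    ``start_date``) and then averaged across the users with data that week;
    SEM is SD/sqrt(n), reported as 0 for single-user weeks (with a warning).
    ``group_by`` names a :class:`UserRecord` attribute (e.g. ``county_fips``
    or ``region``); ``None`` pools the cohort as group ``"all"``.
    """
    if metric not in TRAJECTORY_METRICS:
        raise ValueError(f"metric must be one of {TRAJECTORY_METRICS}, got {metric!r}")
    span = ObservationWindow("trajectory", start_date, end_date)
    rows: list[TrajectoryPoint] = []
    for week in span.weeks():
        per_group: dict[str, list[float]] = {}
        for user in users:
            stream = streams.get(user.user_id)
            if stream is None:
                continue
            try:
                wm = compute_window_metrics(stream, week, thresholds)
            except UndefinedMetricError:
                continue
            group = "all" if group_by is None else str(getattr(user, group_by))
            per_group.setdefault(group, []).append(getattr(wm, metric))
        for group in sorted(per_group):
            vals = np.array(per_group[group])
            if vals.size == 1:
                logger.warning("trajectory %s/%s week %s: single user, SEM set to 0",
                               metric, group, week.start_date)
                sem = 0.0
            else:
                sem = float(vals.std(ddof=1) / math.sqrt(vals.size))
            rows.append(TrajectoryPoint(group, week.start_date, int(vals.size),
                                        float(vals.mean()), sem))
    return pd.DataFrame([vars(r) for r in rows],
                        columns=["group", "week_start", "n", "mean", "sem"])
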