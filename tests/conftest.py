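"""Shared fixtures: hand-built streams and metrics tables for toy cohorts."""
from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from cgmtrends.data_model import SLOT_SECONDS, SLOTS_PER_DAY, GlucoseStream, ObservationWindow
from cgmtrends.metrics import compute_gmi


def make_stream(
    user_id: str,
    start: dt.date,
    day_values: dict[int, tuple[int, int]] | None = None,
    n_days: int = 0,
    glucose: int = 120,
    per_day: int = SLOTS_PER_DAY,
) -> GlucoseStream:
    """Build a stream on the 5-minute grid.

    ``day_values`` maps day offset -> (n_readings, glucose) and overrides the
    uniform ``n_days``/``per_day``/``glucose`` layout.
    """
    if day_values is None:
        day_values = {d: (per_day, glucose) for d in range(n_days)}
    times, values = [], []
    t0 = np.datetime64(start, "s")
    for day in sorted(day_values):
        n, g = day_values[day]
        base = t0 + np.timedelta64(day * 86400, "s")
        times.append(base + (np.arange(n) * SLOT_SECONDS).astype("timedelta64[s]"))
        values.append(np.full(n, g, dtype=np.int16))
    if not times:
        return GlucoseStream(user_id, np.array([], dtype="datetime64[s]"),
                             np.array([], dtype=np.int16))
    return GlucoseStream(user_id, np.concatenate(times), np.concatenate(values))


def metrics_frame(tir_by_user: dict[str, float],
                  mean_glucose: float = 150.0) -> pd.DataFrame:
    """A minimal but schema-complete metrics table from given TIR values."""
    rows = []
    for uid, tir in tir_by_user.items():
        rows.append({
            "window": "toy", "n_readings": 1000, "tir": tir,
            "tbr54": 0.0, "tbr70": (100 - tir) / 2, "tar180": (100 - tir) / 2,
            "tar250": 1.0, "mean_glucose": mean_glucose,
            "sd_glucose": 40.0, "cv": 26.7, "gmi": compute_gmi(mean_glucose),
            "meets_tir_goal": tir >= 70, "meets_tar250_goal": True,
        })
    return pd.DataFrame(rows, index=pd.Index(tir_by_user.keys(), name="user_id"))


@pytest.fixture
def week_window() -> ObservationWindow:
    return ObservationWindow("wk", dt.date(2020, 1, 6), dt.date(2020, 1, 12))


@pytest.fixture
def two_week_window() -> ObservationWindow:
    return ObservationWindow("2wk", dt.date(2020, 1, 6), dt.date(2020, 1, 19))


@pytest.fixture
def pre8_window() -> ObservationWindow:
    return ObservationWindow("pre", dt.date(2020, 1, 6), dt.date(2020, 3, 1))
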