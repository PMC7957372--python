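"""Consensus CGM metrics per user per observation window.

Band metrics are reading-weighted percentages: time in range (TIR) counts
readings in the closed band [70, 180] mg/dL; time-below-range bands are
strict ``<`` and time-above-range bands strict ``>``, so TIR, TBR<70 and
TAR>180 partition every stream exactly.  The glucose management indicator
(GMI) is the standard affine map of mean glucose,

    GMI(%) = 3.31 + 0.02392 * mean_glucose(mg/dL),

and the coefficient of variation is 100 * SD/mean with the n-1 sample SD.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import GlucoseStream, ObservationWindow

GMI_INTERCEPT = 3.31
GMI_SLOPE = 0.02392


class UndefinedMetricError(ValueError):
    """Raised when a metric is requested on too few readings."""


@dataclass(frozen=True)
class MetricThresholds:
    """Band edges (mg/dL) and goal cutoffs (%) for the consensus metrics."""

    tir_low: float = 70.0
    tir_high: float = 180.0
    tbr_level2: float = 54.0
    tar_level2: float = 250.0
    tir_goal: float = 70.0     # meets goal when TIR >= this
    tar250_goal: float = 5.0   # meets goal when TAR>250 < this

    def __post_init__(self) -> None:
        if not (self.tbr_level2 < self.tir_low < self.tir_high < self.tar_level2):
            raise ValueError("thresholds must satisfy tbr2 < low < high < tar2")


DEFAULT_THRESHOLDS = MetricThresholds()


@dataclass
class WindowMetrics:
    """All consensus metrics for one user in one window."""

    user_id: str
    window: str
    n_readings: int
    tir: float
    tbr54: float
    tbr70: float
    tar180: float
    tar250: float
    mean_glucose: float
    sd_glucose: float
    cv: float
    gmi: float
    meets_tir_goal: bool
    meets_tar250_goal: bool


def pct_in_band(
    values: np.ndarray,
    low: float = -np.inf,
    high: float = np.inf,
    low_inclusive: bool = True,
    high_inclusive: bool = True,
) -> float:
    """Percentage of readings inside a glucose band.

    Band edges are inclusive by default (the TIR convention); pass
    ``low_inclusive=False`` / ``high_inclusive=False`` for the strict
    above/below-range bands.
    """
    values = np.asarray(values)
    if values.size == 0:
        raise UndefinedMetricError("band percentage undefined on an empty window")
    lo = values >= low if low_inclusive else values > low
    hi = values <= high if high_inclusive else values < high
    return 100.0 * float(np.count_nonzero(lo & hi)) / values.size


def compute_gmi(mean_glucose: float) -> float:
    """GMI (%) from mean glucose (mg/dL); strictly increasing and affine."""
    if not mean_glucose > 0:
        raise ValueError(f"mean glucose must be positive, got {mean_glucose}")
    return GMI_INTERCEPT + GMI_SLOPE * mean_glucose


def compute_cv(values: np.ndarray) -> float:
    """Coefficient of variation (%), sample SD (n-1) over mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise UndefinedMetricError("CV requires at least two readings")
    mean = float(values.mean())
    if not mean > 0:
        raise UndefinedMetricError("CV undefined for nonpositive mean glucose")
    return 100.0 * float(values.std(ddof=1)) / mean


def compute_window_metrics(
    stream: GlucoseStream,
    window: ObservationWindow,
    thresholds: MetricThresholds = DEFAULT_THRESHOLDS,
) -> WindowMetrics:
    """All consensus metrics for one user's readings inside a window.

    Raises :class:`UndefinedMetricError` if the restriction is empty (such a
    user should already have failed the data-density filters) or has a single
    reading (CV undefined).
    """
    g = stream.restrict(window).glucose.astype(float)
    t = thresholds
    tir = pct_in_band(g, t.tir_low, t.tir_high)
    tbr70 = pct_in_band(g, high=t.tir_low, high_inclusive=False)
    tar180 = pct_in_band(g, low=t.tir_high, low_inclusive=False)
    tar250 = pct_in_band(g, low=t.tar_level2, low_inclusive=False)
    mean = float(g.mean())
    return WindowMetrics(
        user_id=stream.user_id,
        window=window.label,
        n_readings=int(g.size),
        tir=tir,
        tbr54=pct_in_band(g, high=t.tbr_level2, high_inclusive=False),
        tbr70=tbr70,
        tar180=tar180,
        tar250=tar250,
        mean_glucose=mean,
        sd_glucose=float(g.std(ddof=1)),
        cv=compute_cv(g),
        gmi=compute_gmi(mean),
        meets_tir_goal=tir >= t.tir_goal,
        meets_tar250_goal=tar250 < t.tar250_goal,
    )


def metrics_table(
    streams: Mapping[str, GlucoseStream],
    user_ids: list[str],
    window: ObservationWindow,
    thresholds: MetricThresholds = DEFAULT_THRESHOLDS,
):
    """Per-user metrics for a window as a DataFrame indexed by user_id.

    Users with no (or a single) reading in the window are skipped.
    """
    rows = []
    for uid in user_ids:
        stream = streams.get(uid)
        if stream is None:
            continue
        try:
            rows.append(vars(compute_window_metrics(stream, window, thresholds)))
        except UndefinedMetricError:
            continue
    cols = [f.name for f in WindowMetrics.__dataclass_fields__.values()]
    df = pd.DataFrame(rows, columns=cols)
    return df.set_index("user_id")
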