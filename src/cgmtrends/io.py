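"""Readers and writers for the pipeline's CSV tables.

Three external schemas are supported:

* glucose CSV: ``user_id,timestamp,glucose`` (ISO-8601 timestamps, mg/dL);
* user metadata CSV: ``user_id,zip,county_fips,state,median_income,
  first_upload,last_upload,mobile_app``;
* county burden CSV in the NYT covid-19-data layout:
  ``date,county,state,fips,cases,deaths`` with cumulative counts.

Timestamps may carry UTC offsets; they are converted to a single reference
timezone (UTC unless overridden) and held naive thereafter, so calendar-day
and week boundaries are deterministic across the cohort.
"""
from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import GLUCOSE_MAX, GLUCOSE_MIN, GlucoseStream, UserRecord
from .regions import assign_region

logger = logging.getLogger(__name__)

GLUCOSE_COLUMNS = ["user_id", "timestamp", "glucose"]
USER_COLUMNS = [
    "user_id", "zip", "county_fips", "state", "median_income",
    "first_upload", "last_upload", "mobile_app",
]
BURDEN_COLUMNS = ["date", "county", "state", "fips", "cases", "deaths"]


class FormatError(ValueError):
    """A table does not conform to its declared schema."""


class TimestampError(FormatError):
    """Unparseable timestamps; carries the offending 1-based line numbers."""

    def __init__(self, path: str, lines: list[int]):
        self.lines = lines
        shown = ", ".join(map(str, lines[:10]))
        more = "" if len(lines) <= 10 else f" (+{len(lines) - 10} more)"
        super().__init__(f"{path}: unparseable timestamps at lines {shown}{more}")


def _require_columns(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


def read_glucose_csv(path: str | Path, tz: str = "UTC") -> dict[str, GlucoseStream]:
    """Load per-user glucose streams from CSV.

    Rows are sorted by time within user; duplicate (user, timestamp) pairs
    collapse to the first occurrence; glucose outside the reportable
    [40, 400] mg/dL range is dropped.  Both kinds of drop are logged.

    Raises
    ------
    FormatError
        If a required column is missing, or (as :class:`TimestampError`)
        if any timestamp fails to parse — the message lists line numbers.
    """
    path = str(path)
    df = pd.read_csv(path, dtype={"user_id": str})
    _require_columns(df, GLUCOSE_COLUMNS, path)

    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        # +2: one for the header line, one for 0- vs 1-based indexing
        raise TimestampError(path, [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())])
    ts = ts.dt.tz_convert(tz).dt.tz_localize(None)

    glucose = pd.to_numeric(df["glucose"], errors="raise")
    work = pd.DataFrame({"user_id": df["user_id"], "timestamp": ts, "glucose": glucose})

    n0 = len(work)
    work = work[(work["glucose"] >= GLUCOSE_MIN) & (work["glucose"] <= GLUCOSE_MAX)]
    n_range = n0 - len(work)
    work = work.sort_values(["user_id", "timestamp"], kind="stable")
    work = work.drop_duplicates(["user_id", "timestamp"], keep="first")
    n_dup = n0 - n_range - len(work)
    if n_range or n_dup:
        logger.info(
            "%s: dropped %d out-of-range rows and %d duplicate-timestamp rows",
            path, n_range, n_dup,
        )

    streams: dict[str, GlucoseStream] = {}
    for uid, grp in work.groupby("user_id", sort=True):
        streams[str(uid)] = GlucoseStream(
            str(uid),
            grp["timestamp"].to_numpy().astype("datetime64[s]"),
            grp["glucose"].to_numpy().astype(np.int16),
        )
    return streams


def write_glucose_csv(streams: dict[str, GlucoseStream], path: str | Path) -> None:
    """Write streams in the glucose CSV schema (ISO-8601, seconds precision)."""
    frames = []
    for uid in streams:
        s = streams[uid]
        frames.append(pd.DataFrame({
            "user_id": uid,
            "timestamp": np.datetime_as_string(s.times, unit="s"),
            "glucose": s.glucose.astype(int),
        }))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=GLUCOSE_COLUMNS)
    out.to_csv(path, index=False)


def read_user_metadata(
    path: str | Path, region_map: dict[str, str] | None = None
) -> list[UserRecord]:
    """Load user records; each user's region is derived from its state code."""
    path = str(path)
    df = pd.read_csv(path, dtype={"user_id": str, "zip": str, "county_fips": str, "state": str})
    _require_columns(df, USER_COLUMNS, path)
    users = []
    for row in df.itertuples(index=False):
        mobile = str(row.mobile_app).strip().lower() in {"true", "1", "yes", "t"}
        users.append(UserRecord(
            user_id=str(row.user_id),
            zip=str(row.zip).zfill(5),
            county_fips=str(row.county_fips).zfill(5),
            state=str(row.state).upper(),
            median_income=float(row.median_income),
            first_upload=dt.date.fromisoformat(str(row.first_upload)),
            last_upload=dt.date.fromisoformat(str(row.last_upload)),
            mobile_app=mobile,
            region=assign_region(str(row.state), region_map),
        ))
    return users


def write_user_metadata(users: list[UserRecord], path: str | Path) -> None:
    pd.DataFrame([
        {
            "user_id": u.user_id, "zip": u.zip, "county_fips": u.county_fips,
            "state": u.state, "median_income": u.median_income,
            "first_upload": u.first_upload.isoformat(),
            "last_upload": u.last_upload.isoformat(),
            "mobile_app": u.mobile_app,
        }
        for u in users
    ], columns=USER_COLUMNS).to_csv(path, index=False)


def read_county_burden(path: str | Path, as_of: dt.date) -> dict[str, int]:
    """Cumulative deaths per county as of a date.

    For each FIPS the row with the latest date <= ``as_of`` wins; counties
    with no row on or before ``as_of`` are omitted (and logged).
    """
    path = str(path)
    df = pd.read_csv(path, dtype={"fips": str})
    _require_columns(df, BURDEN_COLUMNS, path)
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["fips"] = df["fips"].str.split(".").str[0].str.zfill(5)
    if ((df["deaths"] < 0) | (df["cases"] < df["deaths"])).any():
        raise FormatError(f"{path}: burden rows must satisfy cases >= deaths >= 0")
    all_fips = set(df["fips"])
    eligible = df[df["date"] <= as_of]
    latest = (
        eligible.sort_values("date", kind="stable").groupby("fips", sort=True).tail(1)
    )
    omitted = all_fips - set(latest["fips"])
    if omitted:
        logger.info("%s: %d counties have no row on or before %s", path, len(omitted), as_of)
    return {row.fips: int(row.deaths) for row in latest.itertuples(index=False)}
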