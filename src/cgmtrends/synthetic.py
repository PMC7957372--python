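"""Synthetic CGM cohort generator.

Emulates the statistical structure of a large real-time CGM uploader
population so the whole pipeline can be exercised end to end without any
proprietary data:

* glucose is log-normal within user — CGM distributions are right-skewed —
  with an AR(1) process on the 5-minute log-residuals (default rho 0.95,
  giving a decorrelation time of roughly 100 minutes);
* each user has a latent baseline mean glucose (between-user spread around
  the population mean) and a personal pandemic shift applied as a step
  change on the stay-at-home date, constant thereafter;
* county COVID deaths are log-normal, and a county's standardized log-death
  score couples into its users' shifts (``burden_coupling``), so harder-hit
  counties improve more;
* zip-level median income is log-normal, and its standardized log couples
  into both baseline glucose and the shift (``income_gradient``);
* missingness is a per-day dropout plus a per-slot thinning on observed days.

The default configuration is calibrated so that the marginal pre-window TIR
distribution has mean ~59% and SD ~20 points, and the paired TIR change has
mean ~+2 and SD ~10 points.  Every generated user's ground-truth parameters
are recorded in a truth table for recovery tests.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .data_model import (
    GLUCOSE_MAX,
    GLUCOSE_MIN,
    POST_WINDOW,
    PRE_WINDOW,
    SLOT_SECONDS,
    SLOTS_PER_DAY,
    GlucoseStream,
    ObservationWindow,
    UserRecord,
    months_between,
)
from .io import write_glucose_csv, write_user_metadata
from .regions import assign_region

#: States used round-robin for synthetic counties; covers all five regions.
_STATE_CYCLE = (
    "NY", "CA", "IL", "WA", "CO", "MN", "TN", "TX", "FL", "MA",
    "PA", "OR", "AZ", "WI", "GA", "NJ", "MO", "NC", "UT", "MI",
)

_LOG_INCOME_MU = math.log(70_000.0)
_LOG_INCOME_SIGMA = 0.5


@dataclass
class GeneratorConfig:
    """All knobs of the generative model, with the calibrated defaults.

    Units: glucose quantities in mg/dL; ``burden_coupling`` is mg/dL of
    extra glucose-lowering per SD of county log-deaths; ``income_gradient``
    is mg/dL of baseline lowering per SD of zip log-income (a quarter of it
    also augments the shift); probabilities are per-day / per-slot.
    """

    n_users: int = 2000
    n_counties: int = 40
    seed: int = 0
    pop_mean_glucose: float = 173.3
    between_user_sd: float = 35.9
    within_user_sd: float = 52.0
    ar1_rho: float = 0.95
    pandemic_shift_mean: float = -3.1
    pandemic_shift_sd: float = 13.0
    burden_coupling: float = 3.0
    income_gradient: float = 8.0
    income_shift_frac: float = 0.25
    daily_dropout_prob: float = 0.05
    within_day_missing_frac: float = 0.10
    pandemic_onset: dt.date = dt.date(2020, 3, 22)
    mobile_app_frac: float = 0.93
    late_start_frac: float = 0.10

    def __post_init__(self) -> None:
        if isinstance(self.pandemic_onset, str):
            self.pandemic_onset = dt.date.fromisoformat(self.pandemic_onset)
        if self.n_users < 0 or self.n_counties < 1:
            raise ValueError("need n_users >= 0 and n_counties >= 1")
        for name in ("between_user_sd", "within_user_sd", "pandemic_shift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("daily_dropout_prob", "within_day_missing_frac",
                     "mobile_app_frac", "late_start_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in [0, 1)")

    @property
    def sigma_log(self) -> float:
        """Within-user log-glucose SD implied by the mg/dL within-user SD."""
        cv = self.within_user_sd / self.pop_mean_glucose
        return math.sqrt(math.log1p(cv * cv))

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["pandemic_onset"] = self.pandemic_onset.isoformat()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class TrueUserParams:
    """Ground truth for one generated user, kept for recovery tests."""

    user_id: str
    baseline_mean: float
    shift: float
    county_fips: str
    median_income: float
    tenure_months: int


@dataclass
class SyntheticCohort:
    users: list[UserRecord]
    streams: dict[str, GlucoseStream]
    counties: pd.DataFrame
    deaths: dict[str, int]
    truth: pd.DataFrame
    config: GeneratorConfig


def generate_counties(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Synthetic county table: fips, state, deaths, allocation weight, effect.

    Deaths are log-normal; the latent burden effect is ``burden_coupling``
    times the standardized log of deaths (glucose-lowering, so positive
    coupling means harder-hit counties improve more).  Allocation weights
    are log-normal, giving the skewed county-size distribution under which
    some counties clear a 200-user floor and others do not.
    """
    n = config.n_counties
    fips = [f"{90000 + 2 * i + 1:05d}" for i in range(n)]
    states = [_STATE_CYCLE[i % len(_STATE_CYCLE)] for i in range(n)]
    deaths = np.floor(rng.lognormal(mean=3.3, sigma=1.4, size=n)).astype(int)
    log_d = np.log(np.maximum(deaths, 1))
    sd = log_d.std()
    z = (log_d - log_d.mean()) / sd if sd > 0 else np.zeros(n)
    effect = config.burden_coupling * z
    weight = rng.lognormal(mean=0.0, sigma=1.2, size=n)
    counties = pd.DataFrame({
        "fips": fips,
        "state": states,
        "deaths": deaths,
        "weight": weight / weight.sum(),
        "burden_effect": effect,
    })
    return counties, dict(zip(fips, deaths.tolist()))


def generate_user_stream(
    params: TrueUserParams,
    windows: Sequence[ObservationWindow],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> GlucoseStream:
    """Simulate one user's 5-minute stream over disjoint windows.

    Log-glucose in each window is the user's (possibly shifted) log mean
    plus a stationary AR(1) residual; the shift applies from the pandemic
    onset date onward.  Day-level dropout and slot-level thinning are then
    applied, and values are rounded and clamped to the reportable range.
    """
    sigma = config.sigma_log
    rho = config.ar1_rho
    times_parts: list[np.ndarray] = []
    glucose_parts: list[np.ndarray] = []
    for window in sorted(windows, key=lambda w: w.start_date):
        n_days = window.n_days
        n_slots = n_days * SLOTS_PER_DAY

        day_kept = rng.random(n_days) >= config.daily_dropout_prob
        slot_kept = rng.random(n_slots) >= config.within_day_missing_frac
        innovations = rng.standard_normal(n_slots)

        onset_offset = (config.pandemic_onset - window.start_date).days
        day_shifted = np.arange(n_days) >= onset_offset
        mean_level = params.baseline_mean + params.shift * day_shifted
        mean_level = np.clip(mean_level, 60.0, 380.0)
        mu_day = np.log(mean_level) - 0.5 * sigma * sigma

        if sigma > 0:
            w = innovations * (sigma * math.sqrt(1.0 - rho * rho))
            w[0] = innovations[0] * sigma  # stationary start
            resid = lfilter([1.0], [1.0, -rho], w)
        else:
            resid = np.zeros(n_slots)
        log_g = np.repeat(mu_day, SLOTS_PER_DAY) + resid
        glucose = np.clip(np.rint(np.exp(log_g)), GLUCOSE_MIN, GLUCOSE_MAX)

        keep = slot_kept & np.repeat(day_kept, SLOTS_PER_DAY)
        if not keep.any():
            continue
        t0 = np.datetime64(window.start_date, "s")
        slot_times = t0 + (np.arange(n_slots) * SLOT_SECONDS).astype("timedelta64[s]")
        times_parts.append(slot_times[keep])
        glucose_parts.append(glucose[keep].astype(np.int16))

    if not times_parts:
        return GlucoseStream(params.user_id, np.array([], dtype="datetime64[s]"),
                             np.array([], dtype=np.int16))
    return GlucoseStream(params.user_id,
                         np.concatenate(times_parts), np.concatenate(glucose_parts))


def _draw_user_attributes(
    config: GeneratorConfig,
    counties: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[list[UserRecord], list[TrueUserParams]]:
    n = config.n_users
    users: list[UserRecord] = []
    truths: list[TrueUserParams] = []
    if n == 0:
        return users, truths

    county_idx = rng.choice(len(counties), size=n, p=counties["weight"].to_numpy())
    # two zips per county, each with its own log-normal median income
    zip_codes = {}
    zip_incomes = {}
    for i in range(len(counties)):
        for j in range(2):
            z = f"{10000 + 10 * i + j:05d}"
            zip_codes.setdefault(i, []).append(z)
            zip_incomes[z] = float(np.exp(_LOG_INCOME_MU + _LOG_INCOME_SIGMA
                                          * rng.standard_normal()))
    zip_pick = rng.integers(0, 2, size=n)
    base_noise = rng.standard_normal(n)
    shift_noise = rng.standard_normal(n)
    mobile = rng.random(n) < config.mobile_app_frac
    late = rng.random(n) < config.late_start_frac
    early_days = rng.integers(0, (dt.date(2020, 1, 1) - dt.date(2016, 6, 1)).days + 1, size=n)
    late_days = rng.integers(1, (dt.date(2020, 6, 1) - dt.date(2020, 1, 1)).days + 1, size=n)

    last_upload = dt.date(2020, 6, 14)
    for i in range(n):
        uid = f"u{i:06d}"
        c = counties.iloc[int(county_idx[i])]
        zcode = zip_codes[int(county_idx[i])][int(zip_pick[i])]
        income = zip_incomes[zcode]
        z_inc = (math.log(income) - _LOG_INCOME_MU) / _LOG_INCOME_SIGMA

        baseline = (config.pop_mean_glucose
                    + config.between_user_sd * base_noise[i]
                    - config.income_gradient * z_inc)
        baseline = float(np.clip(baseline, 60.0, 380.0))
        shift = (config.pandemic_shift_mean
                 + config.pandemic_shift_sd * shift_noise[i]
                 - float(c["burden_effect"])
                 - config.income_shift_frac * config.income_gradient * z_inc)

        if late[i]:
            first = dt.date(2020, 1, 1) + dt.timedelta(days=int(late_days[i]))
        else:
            first = dt.date(2016, 6, 1) + dt.timedelta(days=int(early_days[i]))
        users.append(UserRecord(
            user_id=uid, zip=zcode, county_fips=str(c["fips"]), state=str(c["state"]),
            median_income=income, first_upload=first, last_upload=last_upload,
            mobile_app=bool(mobile[i]), region=assign_region(str(c["state"])),
        ))
        truths.append(TrueUserParams(
            user_id=uid, baseline_mean=baseline, shift=float(shift),
            county_fips=str(c["fips"]), median_income=income,
            tenure_months=months_between(first, last_upload),
        ))
    return users, truths


def generate_cohort(
    config: GeneratorConfig,
    windows: Sequence[ObservationWindow] = (PRE_WINDOW, POST_WINDOW),
) -> SyntheticCohort:
    """Generate a fully reproducible cohort: users, streams, counties, truth.

    All randomness flows from ``config.seed`` through named substreams
    (counties, user attributes, one per-user stream substream), so results
    are byte-identical for identical configs.
    """
    ss = np.random.SeedSequence(config.seed)
    ss_counties, ss_users, ss_streams = ss.spawn(3)
    counties, deaths = generate_counties(config, np.random.default_rng(ss_counties))
    users, truths = _draw_user_attributes(config, counties, np.random.default_rng(ss_users))

    streams: dict[str, GlucoseStream] = {}
    child_seeds = ss_streams.spawn(config.n_users)
    for params, child in zip(truths, child_seeds):
        streams[params.user_id] = generate_user_stream(
            params, windows, config, np.random.default_rng(child))

    truth = pd.DataFrame(
        [asdict(t) for t in truths],
        columns=["user_id", "baseline_mean", "shift", "county_fips",
                 "median_income", "tenure_months"],
    )
    return SyntheticCohort(users, streams, counties, deaths, truth, config)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path,
                 write_streams: bool = True, as_of: dt.date = dt.date(2020, 5, 21)) -> None:
    """Emit the cohort in the pipeline's external CSV schemas.

    Writes users.csv, county_burden.csv (one cumulative row per county dated
    ``as_of``), truth_table.csv, config.yaml and — optionally, these files
    are large — glucose.csv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_user_metadata(cohort.users, out / "users.csv")
    burden = pd.DataFrame({
        "date": as_of.isoformat(),
        "county": [f"County {f}" for f in cohort.counties["fips"]],
        "state": cohort.counties["state"],
        "fips": cohort.counties["fips"],
        "cases": (cohort.counties["deaths"] * 20 + 50).astype(int),
        "deaths": cohort.counties["deaths"],
    })
    burden.to_csv(out / "county_burden.csv", index=False)
    cohort.truth.to_csv(out / "truth_table.csv", index=False)
    cohort.config.to_yaml(out / "config.yaml")
    if write_streams:
        write_glucose_csv(cohort.streams, out / "glucose.csv")
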