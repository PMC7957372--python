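"""Stratified summaries and the county-level disease-burden correlation.

Strata are zip-level median-income bands, the five CDC-designated regions,
or device-tenure bands; each reports pre- and post-window mean TIR with
normal-approximation 95% confidence intervals.  The ecological correlation
relates log cumulative COVID deaths to the fraction of users per county with
a clinically meaningful (>= 5 point) TIR increase, restricted to counties
with at least 200 included users.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .comparison import CATEGORY_INCREASE
from .data_model import UNASSIGNED_REGION, UserRecord
from .regions import REGION_NAMES

logger = logging.getLogger(__name__)

MIN_COUNTY_USERS = 200

#: Right-open income band edges (USD/year); only the $150k edge is anchored
#: to the reported ">$150,000" band, the rest are configurable defaults.
INCOME_EDGES = (50_000.0, 100_000.0, 150_000.0)
#: Tenure band edges (months); only ">=37" is anchored to the reported bands.
TENURE_EDGES = (13, 25, 37)

SCHEMES = ("income_bands", "region", "tenure_bands")

Z_95 = 1.96


@dataclass(frozen=True)
class CountySummary:
    fips: str
    n_users: int
    fraction_meaningful_increase: float
    deaths: int


@dataclass(frozen=True)
class StratumSummary:
    stratum: str
    n: int
    tir_pre_mean: float
    tir_pre_lo: float
    tir_pre_hi: float
    tir_post_mean: float
    tir_post_lo: float
    tir_post_hi: float


def county_improver_fractions(
    changes: pd.DataFrame,
    users: Sequence[UserRecord],
    deaths: Mapping[str, int],
    min_users: int = MIN_COUNTY_USERS,
) -> list[CountySummary]:
    """Per-county fraction of users with a meaningful TIR increase.

    Only counties with at least ``min_users`` users in ``changes`` are
    returned; counties absent from the ``deaths`` map get 0 deaths.
    """
    fips_of = {u.user_id: u.county_fips for u in users}
    county = pd.Series({uid: fips_of.get(uid) for uid in changes.index}, name="fips")
    grouped = changes.assign(fips=county).dropna(subset=["fips"]).groupby("fips", sort=True)
    out = []
    for fips, grp in grouped:
        if len(grp) < min_users:
            continue
        frac = float((grp["category"] == CATEGORY_INCREASE).mean())
        out.append(CountySummary(str(fips), len(grp), frac, int(deaths.get(fips, 0))))
    return out


def burden_correlation(summaries: Sequence[CountySummary]) -> tuple[float, float, int]:
    """Pearson correlation of log(deaths) with the improver fraction.

    Natural log is used (r is invariant to the base).  Zero-death counties
    are dropped (logged).  Returns ``(r, two-sided p, n_counties)``; the
    p-value comes from the t transform with n-2 degrees of freedom.
    """
    usable = [s for s in summaries if s.deaths > 0]
    n_zero = len(summaries) - len(usable)
    if n_zero:
        logger.info("burden correlation: dropped %d zero-death counties", n_zero)
    n = len(usable)
    if n < 3:
        raise ValueError(f"burden correlation needs >= 3 usable counties, got {n}")
    x = np.log([s.deaths for s in usable])
    y = np.array([s.fraction_meaningful_increase for s in usable])
    xc, yc = x - x.mean(), y - y.mean()
    sxx, syy = float(xc @ xc), float(yc @ yc)
    if sxx == 0 or syy == 0:
        raise ValueError("burden correlation degenerate: zero variance")
    r = float(xc @ yc) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, p, n


def _income_band(income: float, edges: Sequence[float]) -> str:
    labels = _income_labels(edges)
    for i, edge in enumerate(edges):
        if income < edge:
            return labels[i]
    return labels[-1]


def _income_labels(edges: Sequence[float]) -> list[str]:
    def k(v: float) -> str:
        return f"${v / 1000:.0f}k"

    labels = [f"<{k(edges[0])}"]
    labels += [f"{k(a)}-{k(b)}" for a, b in zip(edges[:-1], edges[1:])]
    labels.append(f">{k(edges[-1])}")
    return labels


def _tenure_band(months: int, edges: Sequence[int]) -> str:
    labels = _tenure_labels(edges)
    for i, edge in enumerate(edges):
        if months < edge:
            return labels[i]
    return labels[-1]


def _tenure_labels(edges: Sequence[int]) -> list[str]:
    labels = [f"<{edges[0]} mo"]
    labels += [f"{a}-{b - 1} mo" for a, b in zip(edges[:-1], edges[1:])]
    labels.append(f">={edges[-1]} mo")
    return labels


def stratum_labels(scheme: str,
                   income_edges: Sequence[float] = INCOME_EDGES,
                   tenure_edges: Sequence[int] = TENURE_EDGES) -> list[str]:
    """Ordered stratum labels for a scheme (excluding ``unknown``)."""
    if scheme == "income_bands":
        return _income_labels(income_edges)
    if scheme == "tenure_bands":
        return _tenure_labels(tenure_edges)
    if scheme == "region":
        return list(REGION_NAMES) + [UNASSIGNED_REGION]
    raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")


def assign_stratum(user: UserRecord, scheme: str,
                   income_edges: Sequence[float] = INCOME_EDGES,
                   tenure_edges: Sequence[int] = TENURE_EDGES) -> str:
    """The single stratum a user belongs to under a scheme."""
    if scheme == "income_bands":
        if not np.isfinite(user.median_income):
            return "unknown"
        return _income_band(user.median_income, income_edges)
    if scheme == "tenure_bands":
        return _tenure_band(user.tenure_months, tenure_edges)
    if scheme == "region":
        return user.region
    raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")


def stratify(
    users: Sequence[UserRecord],
    pre: pd.DataFrame,
    post: pd.DataFrame,
    scheme: str,
    income_edges: Sequence[float] = INCOME_EDGES,
    tenure_edges: Sequence[int] = TENURE_EDGES,
) -> list[StratumSummary]:
    """Pre/post mean TIR with 95% CIs per stratum.

    Every user present in both metrics tables lands in exactly one stratum;
    users whose stratum variable is missing go to ``unknown`` (logged).
    Strata are reported in their natural order, empty strata omitted.
    """
    common = pre.index.intersection(post.index)
    members: dict[str, list[str]] = {}
    for user in users:
        if user.user_id not in common:
            continue
        label = assign_stratum(user, scheme, income_edges, tenure_edges)
        members.setdefault(label, []).append(user.user_id)
    if "unknown" in members:
        logger.info("stratify(%s): %d users with missing stratum variable",
                    scheme, len(members["unknown"]))

    order = stratum_labels(scheme, income_edges, tenure_edges) + ["unknown"]
    out = []
    for label in order:
        ids = members.get(label)
        if not ids:
            continue
        n = len(ids)
        row: dict[str, float] = {}
        for name, table in (("pre", pre), ("post", post)):
            vals = table.loc[ids, "tir"].to_numpy()
            mean = float(vals.mean())
            half = 0.0 if n < 2 else Z_95 * float(vals.std(ddof=1)) / math.sqrt(n)
            row[f"{name}_mean"], row[f"{name}_half"] = mean, half
        out.append(StratumSummary(
            stratum=label, n=n,
            tir_pre_mean=row["pre_mean"],
            tir_pre_lo=row["pre_mean"] - row["pre_half"],
            tir_pre_hi=row["pre_mean"] + row["pre_half"],
            tir_post_mean=row["post_mean"],
            tir_post_lo=row["post_mean"] - row["post_half"],
            tir_post_hi=row["post_mean"] + row["post_half"],
        ))
    return out


def strata_table(summaries: Sequence[StratumSummary]) -> pd.DataFrame:
    cols = ["stratum", "n", "tir_pre_mean", "tir_pre_lo", "tir_pre_hi",
            "tir_post_mean", "tir_post_lo", "tir_post_hi"]
    return pd.DataFrame([vars(s) for s in summaries], columns=cols)
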