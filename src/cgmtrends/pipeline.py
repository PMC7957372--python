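"""End-to-end pipeline: generate (or ingest) → filter → metrics → compare →
stratify, with every stage's counts logged and all outputs written under one
directory.  A run is fully reproducible from the config seed.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import comparison, stratification
from .data_model import LATE_WINDOW, POST_WINDOW, PRE_WINDOW, ObservationWindow
from .filtering import DensityRule, filter_cohort
from .metrics import DEFAULT_THRESHOLDS, MetricThresholds, metrics_table
from .synthetic import GeneratorConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; windows default to the study intervals."""

    pre_window: ObservationWindow = PRE_WINDOW
    post_window: ObservationWindow = POST_WINDOW
    late_window: ObservationWindow = LATE_WINDOW
    density: DensityRule = field(default_factory=DensityRule)
    thresholds: MetricThresholds = field(default_factory=MetricThresholds)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    meaningful_threshold: float = comparison.MEANINGFUL_TIR_CHANGE
    min_county_users: int = stratification.MIN_COUNTY_USERS
    burden_as_of: dt.date = dt.date(2020, 5, 21)
    schemes: tuple[str, ...] = stratification.SCHEMES
    write_streams: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        for key in ("pre_window", "post_window", "late_window"):
            if key in raw:
                label = key.removesuffix("_window")
                kwargs[key] = ObservationWindow.parse(label, raw.pop(key))
        if "density" in raw:
            kwargs["density"] = DensityRule(**raw.pop("density"))
        if "thresholds" in raw:
            kwargs["thresholds"] = MetricThresholds(**raw.pop("thresholds"))
        if "generator" in raw:
            kwargs["generator"] = GeneratorConfig(**raw.pop("generator"))
        if "burden_as_of" in raw:
            kwargs["burden_as_of"] = dt.date.fromisoformat(raw.pop("burden_as_of"))
        if "schemes" in raw:
            kwargs["schemes"] = tuple(raw.pop("schemes"))
        kwargs.update(raw)
        return cls(**kwargs)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute every stage on a synthetic cohort and write all artifacts.

    Returns the summary dict (also written as ``summary.json``); the
    ``artifacts`` entry lists every file written.  Any stage failure is
    re-raised annotated with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    summary: dict[str, Any] = {"seed": config.generator.seed}

    def _save_df(df: pd.DataFrame, name: str, index: bool = False) -> None:
        df.to_csv(out / name, index=index)
        artifacts.append(name)

    stage = "generate"
    try:
        cohort = generate_cohort(config.generator, (config.pre_window, config.post_window))
        write_cohort(cohort, out, write_streams=config.write_streams,
                     as_of=config.burden_as_of)
        artifacts += ["users.csv", "county_burden.csv", "truth_table.csv", "config.yaml"]
        if config.write_streams:
            artifacts.append("glucose.csv")
        summary["n_users_generated"] = len(cohort.users)
        logger.info("generate: %d users, %d counties", len(cohort.users), len(cohort.counties))

        stage = "filter"
        included, reports = filter_cohort(
            cohort.users, cohort.streams, config.pre_window, config.post_window,
            config.density)
        _save_df(pd.DataFrame([dataclasses.asdict(r) for r in reports]
                              or [], columns=["user_id", "passed", "failure_reasons"]),
                 "inclusion_report.csv")
        summary["n_included"] = len(included)
        logger.info("filter: %d of %d users included", len(included), len(cohort.users))

        stage = "metrics"
        ids = [u.user_id for u in included]
        pre = metrics_table(cohort.streams, ids, config.pre_window, config.thresholds)
        post = metrics_table(cohort.streams, ids, config.post_window, config.thresholds)
        _save_df(pre, "metrics_pre.csv", index=True)
        _save_df(post, "metrics_post.csv", index=True)

        stage = "compare"
        comp = comparison.summarize_comparison(pre, post, config.meaningful_threshold)
        changes = comparison.paired_changes(pre, post, config.meaningful_threshold)
        _save_df(changes, "changes.csv", index=True)
        (out / "comparison.json").write_text(json.dumps(comp.to_dict(), indent=2, sort_keys=True))
        artifacts.append("comparison.json")
        for label, table in (("pre", pre), ("post", post)):
            _save_df(comparison.tir_histogram(table["tir"]), f"tir_histogram_{label}.csv")
        summary["comparison"] = comp.to_dict()

        stage = "stratify"
        strata: dict[str, Any] = {}
        for scheme in config.schemes:
            rows = stratification.stratify(included, pre, post, scheme)
            _save_df(stratification.strata_table(rows), f"strata_{scheme}.csv")
            strata[scheme] = [dataclasses.asdict(r) for r in rows]
        summary["strata"] = strata

        county_rows = stratification.county_improver_fractions(
            changes, included, cohort.deaths, config.min_county_users)
        _save_df(pd.DataFrame([dataclasses.asdict(c) for c in county_rows] or [],
                              columns=["fips", "n_users", "fraction_meaningful_increase",
                                       "deaths"]),
                 "county_summaries.csv")
        try:
            r, pval, n_counties = stratification.burden_correlation(county_rows)
            corr = {"r": r, "p_value": pval, "n_counties": n_counties}
        except ValueError as exc:
            corr = {"error": str(exc), "n_counties": len(county_rows)}
        (out / "correlation.json").write_text(json.dumps(corr, indent=2, sort_keys=True))
        artifacts.append("correlation.json")
        summary["burden_correlation"] = corr
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary["artifacts"] = sorted(artifacts)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "report.txt").write_text(_render_report(summary))
    return summary


def _render_report(summary: dict[str, Any]) -> str:
    c = summary.get("comparison", {})
    corr = summary.get("burden_correlation", {})
    lines = [
        "CGM cohort pre/post comparison",
        "==============================",
        f"users generated: {summary.get('n_users_generated')}",
        f"users included:  {summary.get('n_included')} (paired n = {c.get('n')})",
        "",
        f"TIR:  {c.get('tir_pre_mean', float('nan')):.1f} ({c.get('tir_pre_sd', float('nan')):.1f})%"
        f" -> {c.get('tir_post_mean', float('nan')):.1f} ({c.get('tir_post_sd', float('nan')):.1f})%",
        f"mean glucose: {c.get('mean_glucose_pre_mean', float('nan')):.1f}"
        f" -> {c.get('mean_glucose_post_mean', float('nan')):.1f} mg/dL",
        f"GMI:  {c.get('gmi_pre_mean', float('nan')):.2f} -> {c.get('gmi_post_mean', float('nan')):.2f} %",
        f"delta TIR: mean {c.get('delta_tir_mean', float('nan')):.1f}"
        f" (SD {c.get('delta_tir_sd', float('nan')):.1f}) points,"
        f" t = {c.get('t_statistic', float('nan')):.2f}, p = {c.get('p_value', float('nan')):.3g}",
        f"improved (delta > 0): {100 * c.get('fraction_improved', float('nan')):.1f}%",
        f"meaningful increase (>= +5): {100 * c.get('fraction_meaningful_increase', float('nan')):.1f}%",
        f"meaningful decrease (<= -5): {100 * c.get('fraction_meaningful_decrease', float('nan')):.1f}%",
        f"TIR >= 70% goal: {100 * c.get('tir_goal_pre', float('nan')):.1f}%"
        f" -> {100 * c.get('tir_goal_post', float('nan')):.1f}%",
        "",
    ]
    if "r" in corr:
        lines.append(
            f"county burden correlation: r = {corr['r']:.2f}, p = {corr['p_value']:.3g}"
            f" over {corr['n_counties']} counties")
    else:
        lines.append(f"county burden correlation: {corr.get('error', 'not computed')}")
    lines.append("")
    return "\n".join(lines)
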