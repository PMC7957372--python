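# cgmtrends

Population-scale analytics for real-time continuous glucose monitoring
(CGM) data: did a cohort's glycemic control change between two periods, and
how were those changes distributed across geography, income and device
tenure?

The package is aimed at biostatisticians and epidemiologists working with
uploader populations from 5-minute CGM sensors. It implements, as a tested
reusable pipeline:

- **inclusion filtering** — enrollment cutoff, mobile-app use, monthly
  upload presence, and a data-density rule (≥200 readings/day on ≥4 days of
  every week of each observation window);
- **consensus glycemic metrics** per user per window — time in range
  (TIR, readings in 70–180 mg/dL), level-2 time below range (<54) and above
  range (>250), mean glucose, SD, coefficient of variation
  (CV = 100·SD/mean), and the glucose management indicator
  **GMI(%) = 3.31 + 0.02392 · mean glucose (mg/dL)**;
- **paired pre/post comparison** — per-user TIR change ΔTIR, the dependent
  *t*-test *t* = Δ̄/(s/√n), classification of changes as clinically
  meaningful (|ΔTIR| ≥ 5 percentage points), TIR histograms, and weekly
  mean ± SEM trajectories by county or region;
- **stratification** — pre/post TIR with 95% CIs by zip-level median income
  band, by the five CDC "Integrated Food Safety Centers of Excellence"
  regions, and by device tenure; plus the ecological Pearson correlation
  between log county COVID-19 deaths and the fraction of county users with
  a meaningful TIR increase (counties with ≥200 users);
- a **synthetic cohort generator** whose defaults are calibrated to the
  published population moments (mean TIR ≈ 59%, SD ≈ 20; mean glucose
  173.3 mg/dL shifting by −3.1), so every stage is exercised end to end
  without any proprietary data, with ground truth recorded for recovery
  tests.

## Worked example

One command generates a 2,000-user synthetic cohort, applies the inclusion
filters, computes metrics over the two 8-week windows (Jan 6 – Mar 1 and
Apr 20 – Jun 14, 2020), and runs the paired comparison and stratifications:

```bash
cgmtrends run --n-users 2000 --seed 1 --min-county-users 50 --out-dir demo/
```

prints (from `demo/report.txt`):

```
CGM cohort pre/post comparison
==============================
users generated: 2000
users included:  1557 (paired n = 1557)

TIR:  57.7 (21.3)% -> 59.3 (21.9)%
mean glucose: 176.0 -> 172.1 mg/dL
GMI:  7.52 -> 7.43 %
delta TIR: mean 1.6 (SD 8.9) points, t = 7.19, p = 9.72e-13
improved (delta > 0): 58.9%
meaningful increase (>= +5): 32.9%
meaningful decrease (<= -5): 19.0%
TIR >= 70% goal: 33.4% -> 38.2%

county burden correlation: r = 0.07, p = 0.86 over 9 counties
```

Reading this: 1,557 of 2,000 generated users met the inclusion criteria
(the generator plants late starters, receiver-only users and sparse
uploaders on purpose). Mean TIR rose 1.6 points, mean glucose fell
3.9 mg/dL (GMI 7.52% → 7.43%), 58.9% of users improved at all and 32.9%
improved by the clinically meaningful ≥5 points. The burden correlation is
computed over only 9 counties at this cohort size, so its sampling spread
is wide; with the default coupling the expected sign is positive and tests
verify it is recovered reliably across seeds. Per-user metrics, per-stratum
tables, histograms and the inclusion report are written alongside as
CSV/JSON (`summary.json` lists every artifact).

The stages are also individual subcommands operating on plain CSV tables —
`generate`, `filter`, `metrics`, `compare`, `stratify`, `burden` — and the
same functionality is importable from Python (`cgmtrends.filter_cohort`,
`cgmtrends.compute_window_metrics`, `cgmtrends.summarize_comparison`, …).

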