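# Methods

## Problem and scope

The pipeline asks a paired question about a population of continuous
glucose monitoring (CGM) uploaders: for the same users, how did consensus
glycemic metrics change between a pre-period and a post-period, and how did
those changes distribute across counties, CDC regions, income bands and
device tenure? The canonical windows are the 8 weeks ending March 1, 2020
(prepandemic) and the 8 weeks ending June 14, 2020 (intrapandemic), with a
relaxed-density late window ending August 9, 2020 supported as a
configuration variant.

Real uploader data of this kind are proprietary, so the package ships a
synthetic cohort generator that emulates the relevant statistical structure
and records ground truth. All statistical claims made by the test suite are
claims about that generative model, not about any real population.

## Metric conventions

- Band metrics are **reading-weighted**: each sensor value counts equally.
  At a near-uniform 5-minute cadence this coincides with time-weighting.
- TIR uses the **closed** band [70, 180] mg/dL; above-range bands are
  strict `>` and below-range bands strict `<`, so TIR + TBR<70 + TAR>180
  = 100 exactly on every stream. The level-2 bands (<54, >250) nest inside
  the level-1 bands by construction. Published band conventions do not
  always state endpoint inclusivity; the choice here is the consensus one
  and is exposed via `MetricThresholds`.
- GMI(%) = 3.31 + 0.02392 × mean glucose (mg/dL), kept at full precision
  internally and reported to 2 decimals; band percentages are reported to
  1 decimal.
- CV and cohort SDs use the n−1 sample convention throughout.
- The paired test is the dependent-samples *t*-test on per-user ΔTIR,
  two-sided, df = n−1. A zero-variance change distribution (e.g. post
  identical to pre) is reported as NaN t/p with a warning rather than an
  error, so degenerate cohorts still summarize.
- The burden correlation is Pearson *r* between **natural** log county
  deaths and the county fraction of meaningful improvers; *r* is invariant
  to the log base and to scaling deaths by a positive constant (both
  tested). Zero-death counties are dropped rather than offset, because an
  additive offset would change *r*. The p-value uses the t transform with
  n−2 df.
- Stratum confidence intervals are normal-approximation mean ± 1.96·SD/√n.
  SEM for a single-user trajectory week is reported as 0 with a warning
  rather than dropping the point.

## Timezone and calendar conventions

Timestamps may arrive with UTC offsets; ingest converts everything to one
configurable reference timezone (default UTC) and treats it as naive
thereafter. Day boundaries, daily counts, months and weeks are all computed
in that single reference frame, which keeps inclusion decisions
deterministic for a cohort spanning four U.S. timezones. No published
convention exists for this choice; a single global frame is the simplest
defensible one.

Observation windows must span whole weeks; weeks are anchored at the window
start date (January 6, 2020 is a Monday, so the canonical windows' weeks
are Mon–Sun calendar weeks).

## Inclusion rule details

A user is included iff: first upload on or before January 1, 2020
(inclusive); mobile-app uploader; at least one reading in every month
January–June 2020; and the density rule holds in both windows. The density
rule's default reading — at least `min_days_per_week` qualifying days
(≥200 readings) in **every** 7-day week of the window — is the strictest
literal interpretation; an averaged variant (`scope="per_window"`, ≥4×8
qualifying days anywhere in an 8-week window) is provided because the
published description does not disambiguate the two. Relaxing the rule can
only add users (tested as a monotonicity property).

## The generative model

Per reading, glucose is log-normal within user with an AR(1) process on the
5-minute log residuals:

    log g_t = log(m_day) − σ²/2 + e_t,   e_t = ρ e_{t−1} + w_t

with ρ = 0.95 (decorrelation time ≈ 100 min) and σ chosen so the
within-user CV matches `within_user_sd / pop_mean_glucose` (default
52/173.3 ≈ 30%). The −σ²/2 correction makes E[g] equal the user's intended
mean level m. Values are rounded to integer mg/dL and clamped to the
sensor-reportable [40, 400]; rounding slightly widens the effective TIR
band (a reading of 70 covers continuous glucose ≥ 69.5), which the test
oracle accounts for. No published within-user temporal statistics exist for
this population; the AR(1)-lognormal choice is a modeling decision that
produces realistic CV without a meal/insulin simulation.

Per user, the day-level mean is a baseline plus a **step shift** on the
stay-at-home date (March 22, 2020 — a single national date standing in for
the county-specific orders of March 19–22), constant thereafter:

    baseline = pop_mean + between_sd·Z − income_gradient·z_income
    shift    = shift_mean + shift_sd·Z′ − burden_coupling·z_county
               − 0.25·income_gradient·z_income

where z_income standardizes log zip median income (log-normal, median
$70k, log-SD 0.5) and z_county standardizes log county deaths (log-normal
across counties). Negative shift means falling glucose, i.e. improvement,
so positive coupling makes harder-hit counties improve more and a positive
income gradient makes wealthier zips both start better and improve more.
The income effect on the shift is fixed at a quarter of its baseline
effect; the published account implies both effects exist but quantifies
neither, so one parameter with a fixed ratio keeps the model identifiable.
Users are allocated to counties with log-normal weights, so county sizes
are skewed and a user floor (e.g. ≥200) separates large from small
counties. Tenure is a mixture over first-upload dates from mid-2016 to the
cutoff (plus a planted late-starter fraction), which populates all four
tenure bands including ≥37 months.

### Calibration

Defaults are calibrated to the published population moments, not fitted to
any output of this package: population mean glucose 173.3 mg/dL and
between-user SD 35.9 are the printed cohort moments; the mean shift
−3.1 mg/dL is the printed mean-glucose change; shift SD 13 mg/dL maps
through the band model to a ΔTIR SD near 10 points. Under these defaults
the marginal pre-window TIR distribution has mean ≈ 58–59% and SD ≈ 21
(verified against a closed-form lognormal oracle of the same marginal), and
the meaningful-improver fraction lands near 33%. Because TIR is a concave
function of mean glucose near its peak, the dispersion of per-user shifts
drags the implied mean ΔTIR (≈ +1.5 points) slightly below the value a
deterministic −3.1 mg/dL shift would give; the generator is calibrated in
glucose units, and exact reproduction of change-distribution fractions is
explicitly not a design target.

### What the generator does not emulate

No diurnal or meal structure, no insulin dynamics, no weekday/weekend
cycles, no gradual (non-step) behavior change, no correlation between
missingness and glycemia, and no demographic structure (age, diabetes
type, race/ethnicity) — the last mirroring a stated limitation of
population uploader data generally. Passing tests therefore demonstrate
correctness of the pipeline's accounting and statistics under a plausible
stochastic model, not fidelity to any real cohort's dynamics.

## Region and geography fixtures

The five CDC "Integrated Food Safety Centers of Excellence" regions are
shipped as a packaged YAML fixture assigning every state, DC, PR, VI and
Guam to the region of its hub (Colorado, Minnesota, New York, Tennessee,
Washington). The published material gives only the region sizes (10, 10,
12+DC, 11+PR+VI, 7+GU); the fixture is a synthetic, geographically
contiguous assignment consistent with those counts and replaceable via
`load_region_map(path)`. County assignment reads the county FIPS directly
from user metadata; no zip→county crosswalk is shipped.

## Problem sizes used by the test suite

Unit and property tests run on toy fixtures (tens of users, 1–2-week
windows). The statistical acceptance checks use a 2,000-user cohort over
the full 8-week windows for shift recovery (the estimate is compared to the
truth-table mean within 3 Monte-Carlo SEs), and 200 simulated 80-user
cohorts over 2-week windows for the type-I-error check (rejections at
α = 0.05 must fall inside the exact binomial 95% band). Two-week windows
are statistically equivalent for these purposes because per-user window
means are unbiased at any multiple of 7 days; they simply widen the
Monte-Carlo SEs the assertions already use.

## Known limitations

- The region fixture's state membership is synthetic (counts-consistent).
- Income-band edges other than $150k and tenure edges other than 37 months
  are conventional defaults, not anchored to published values.
- The ecological burden correlation is an association across county
  aggregates; nothing here supports individual-level causal reading.
- Streams are held in memory; cohorts far beyond ~10⁵ users × 16 weeks
  would need a chunked ingest path.
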