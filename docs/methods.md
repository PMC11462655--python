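# Methods

## The chart

For one city and a chosen study year, the monthly IMR series is

    imr(y, m) = 1000 · deaths(y, m) / births(y, m),   undefined when births = 0.

The baseline window is the `window_years` (default 10) calendar years
strictly preceding the study year; study-year data never enters the
baseline. For each calendar month m separately, MD(m) is the mean and
SD(m) the sample standard deviation (n−1 denominator) of the defined
baseline values of that month; a month with fewer than `min_years`
(default 3) usable values gets undefined statistics. Control limits are

    UCL(m) = MD(m) + z·SD(m),    LCL(m) = max(0, MD(m) − z·SD(m)),

with z = 1.96 by default (the central-95% normal multiplier); the lower
limit is clipped because a rate cannot be negative. A study-year
observation strictly above the UCL or strictly below the LCL is an alert;
equality with a limit is not (an arbitrary but fixed convention). A month
with an undefined observation or undefined limits is "unassessable".

Per-month baselines (12 MD/SD pairs) are the default because the chart is
read month-by-month — which month is expected high, which low; a pooled
single-band mode is available (`pooled=True`). The estimator choices the
method leaves open were resolved as: sample SD (the conventional small-n
estimator), calendar-month aggregation of counts with IMR as a ratio of
sums (a mean of daily ratios is undefined whenever a day has zero births),
and a generic fixed-window block mean `aggregate_mean` retained for
ordinary rate series (identity at window 1; trailing partial windows are
dropped, since a partial-window mean is not comparable to full ones).

Known epidemic periods must be removed from the baseline before limits
are computed — otherwise the channel is widened by the anomalies it should
flag. Removal is caller-supplied (an exclusion list of city/year/month
triples); because no general rule exists for discovering them, automatic
trimming is off by default and available only as an explicit one-pass
option (`trim=True`: drop baseline points outside a provisional z-band,
recompute once).

### Chart status

A chart is summarized as `ok`, `degenerate`, or `insufficient_history`:

- `insufficient_history`: more than `max_undefined_months` (default 3) of
  the 12 months have undefined baseline statistics.
- `degenerate`: at least `min_degenerate_months` (default 6) months have
  SD = 0 with MD = 0 — an all-zero death history collapses the channel to
  a point at zero, so any death at all fires an alert. SD = 0 with MD > 0
  (a genuinely constant nonzero history) is not treated as degeneracy.

The thresholds are conventions, configurable, chosen so that a chart is
only called unusable when at least half (degenerate) or a quarter
(insufficient) of the year carries no information.

## Population strata and consistency labels

Cities map to the six IBGE population-size classes (≤10,000 up to
>500,000); a population of exactly 500,000 is assigned to the fifth class,
a documented convention at an ambiguous boundary. Per stratum and study
year the package reports totals, the pooled rate 1000·Σdeaths/Σbirths, and
the *unweighted* cross-city mean and SD of annual city IMR (zero-birth
cities excluded from the statistics but counted). The cross-city SD — not
the pooled rate, which is dominated by the largest cities — drives the
five-step consistency label (consistent … inconsistent) through ordered SD
bin edges, default (3.5, 5.5, 8, 12) per 1,000 live births. The defaults
reproduce the canonical label gradient of the national municipal profile
from its six published stratum SDs; the edges are configuration, not
constants, since only the labels, never numeric thresholds, are published.
An undefined SD (fewer than two cities with births) is labelled
inconsistent: with no dispersion estimate there is no basis for trust.

## The synthetic-data generator

Each simulated city has a fixed population, an annual crude birth rate and
a true infant mortality risk. Monthly live births are Poisson with mean
`population · rate / 12000` — the simplest count law consistent with a
per-1,000 annual rate; monthly infant deaths are Binomial(births, p) with

    p = (true_imr / 1000) · (1 + a · sin(2π(month−1)/12)),

so deaths ≤ births by construction and a zero-birth month has zero deaths.
Defaults, fixed once: birth rate ~ Normal(13.5, 1.5) per 1,000/year
(floored at 5), true IMR ~ Normal(11.6, 2.0) per 1,000 births (clamped to
[1, 999]), seasonal amplitude a = 0.1 — magnitudes of the national
municipal profile. Populations are log-uniform within each stratum's
bounds, floored at 1,500 and capped at 6,000,000 for the open-ended top
stratum (the scale of the largest Brazilian municipalities). Per-city RNG
streams are keyed on (master seed, stratum, city index), so enlarging one
stratum never perturbs another and fixed seeds give byte-identical
datasets.

Epidemics are injected as ground truth for power studies: targeted
(city, year, month) cells have deaths re-drawn with the per-birth
probability multiplied by a factor ≥ 1 (clamped at 1); untargeted cells
are untouched.

What the generator deliberately does **not** emulate: deaths are attached
to same-month births, whereas real infant deaths lag their birth cohort by
up to a year — the ratio-instability mechanism under study does not depend
on that lag; there is no inter-city spatial correlation, no secular trend
or demographic projection, and no under-registration (real birth/death
systems have imperfect, time-varying coverage). Passing tests therefore
demonstrate the small-denominator mechanism and the chart's operating
characteristics under a clean stationary process, not the additional
biases real vital-statistics series carry.

## Reliability evaluation

`empirical_coverage` is the idealized benchmark: with known μ, σ the
fraction of normal draws inside μ ± 1.96σ converges to 0.95.
`false_alert_rate` runs the full pipeline (simulate → monthly IMR →
baseline → limits → alerts) on stable cities and reports, per stratum, the
fraction of *assessable* study-year months flagged in either direction,
with the unassessable fraction alongside — in small cities undefined
months would otherwise dominate the denominator and mask the phenomenon.
Because limits are estimated from ~10 baseline points per month rather
than known, the false-alert rate sits above the nominal 5% even in large
cities (≈9–10% at defaults) and approaches it as the baseline lengthens.
`detection_power` injects a multiplicative mortality shock into chosen
study-year months of every city (study-year cells are disjoint from the
baseline window) and reports the fraction of injected city-months flagged
"above" — only upward alerts count, the injected anomaly being an
excess-mortality event; at multiplier 1 the injection is a plain re-draw
and power estimates the upward false-alert rate.

Problem sizes: the acceptance run uses 200 cities per stratum over
2009–2019 (ten baseline years plus study year 2019) in one replication —
1,200 cities give stable stratum-level fractions; the analysis drivers use
40 cities per stratum over 2009–2020 with two replications for the
reliability report. Replication seeds are derived deterministically from
the master seed; reports embed seed and replication count.

## Numerical conventions

Undefined values (zero-birth IMRs, thin baselines) are NaN in memory and
the token `NA` on disk, never empty strings or silent zeros — a silent
zero would bias MD downward in exactly the cities where the pathology
lives. Rates are serialized at 4 decimal places; writer → reader
round-trips at that precision. All randomness flows through
`numpy.random.default_rng` seeded explicitly.

## Known limitations

- The chart itself ignores growth/decline trends; a secular trend inflates
  the baseline SD and widens the channel. Reproduced faithfully, not fixed.
- Channel limits depend on the chosen baseline window; 10 years is the
  default, configurable (an 11-year window matching an alternative reading
  of the method's span can be requested via `window_years=11`).
- The consistency bin edges are calibrated to one published profile; other
  settings may warrant different edges (they are plain configuration).
- No CUSUM/EWMA/Bayesian small-area alternatives; this package evaluates
  the plain Shewhart-type channel.
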