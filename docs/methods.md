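# Methods

## The data model

The unit of observation is the CCG *pair-day*: one daily form per pair and
field date, holding depart and return clock times, the household visits
attempted that day, and the timed activity records that fill the day.
Times are whole minutes since midnight — the reporting resolution of the
field forms is one minute, and integer arithmetic avoids any floating-point
time. Activities carry one of six group codes: adherence support (TB /
other disease), client encounter (TB / other disease), home-based care, and
travel. Travel is the only *indirect* group; the other five constitute
direct, at-household service. A visit's duration is the sum of the direct
records linked to it; travel is never attributed to a visit. A *successful*
visit is one with at least one patient interaction; failures carry one of
seven reasons (patient unavailable, wrong address, deceased, relocated,
door locked, refused care, unknown patient), zero patients, and no direct
activity time.

### Quality validation

Field TAM protocols require continuous, consecutive reporting. A form is
excluded when any of the following holds, and the verdict lists every rule
violated:

- **time_gap** — records sorted by start do not tile depart→return (a hole
  before, between, or after records);
- **non_contiguous** — overlapping records, zero/negative durations, or
  return ≤ depart (overnight forms are rejected; field days in these data
  are at most ~6 hours);
- **missing_field** — no activity records, or a successful visit without a
  recorded care purpose;
- **uniform_durations** — three or more records all of identical length, a
  suspicious reporting pattern. The threshold of three avoids flagging
  legitimately short days (a lone out-and-back trip produces two equal
  records easily);
- **other** — linkage violations (travel tied to a household, direct time
  tied to no household or to a failed visit, patient counts inconsistent
  with the outcome).

Retained + excluded always partition the input; the exclusion log carries
one verdict per dropped form.

## The synthetic generator

The generator emulates the structure the analysis assumes, at the operating
points of a two-clinic South African field study (March–October 2018):
clinic 1 peri-urban, 7 pairs, ~14 observation days per pair, visit success
probability 0.973, ~1.8 patients per successful household, travel median
8 min (IQR 5–15); clinic 2 urban informal settlement, 4 pairs, ~15 days per
pair, success 0.715, ~1.2 patients per household, travel median 14 (IQR
8–20). Failure-reason and care-purpose weights are proportional to the
published per-clinic counts; non-travel activity-group weights are
proportional to the published episode counts.

Design choices, where the emulated forms do not pin one down:

- **Durations are log-normal**, parameterized by `mu = ln(median)` and
  `sigma = ln(q3/q1) / (2 z₀.₇₅)`. This pins the median exactly and the
  quartile *ratio*; with an asymmetric printed IQR the two individual
  quartiles cannot also both be matched. Positive support and right skew
  match the observed mean > median in every activity group.
- **Patients per household** are `1 + Poisson(λ)` capped at 5, with λ set
  from the published means (0.8 and 0.2); only means are reported.
- **A day is a renewal process**: draw a field-time target (log-normal,
  clipped to the observed range), then alternate travel legs and visit
  blocks until the target is passed, ending with a return leg. Because a
  stopping-rule day overshoots its threshold by about half a cycle, the
  stopping threshold is lowered by the expected half-cycle (plus the
  expected extra return leg), keeping realized field time centered on the
  drawn target. Nothing is trimmed, so the travel-duration distribution is
  untouched — this matters because the travel median is a calibration
  target.
- **Failed visits** occupy the preceding travel episode (a brief doorstep
  interval is absorbed into it, extending the leg only if it was shorter
  than the doorstep); they never accrue direct activity time.
- **Activities per successful visit** number 1–3, weighted per clinic
  ((0.45, 0.35, 0.20) at clinic 1, one activity always at clinic 2), so
  per-visit durations and the household/travel split land near the
  published ~49.5% and ~35.0% household shares.
- **Corruption** (default probability 0.2 per form, the observed exclusion
  rate): either an interior record is deleted (a time gap) or all records
  are flattened to equal length (the uniform pattern). Everything else is
  valid by construction, so the quality filter's exclusion fraction
  estimates the corruption rate.
- Dates are spread uniformly over the study window; no secular trend is
  injected, so trend analyses should find slopes indistinguishable from
  zero.

What the generator does *not* emulate: spatial structure (travel is drawn,
not routed), correlation between failure reasons and travel time, pair-level
heterogeneity in skill or pace, and weekday/seasonal effects. Passing tests
therefore demonstrate that the analysis recovers known generating
parameters and preserves its invariants — not that real forms are this
well-behaved.

## Workload analysis

Six per-clinic outcomes: (1) field-day length and its household/travel
partition (clinic share = 100 × Σ household / Σ field minutes; the range is
the same ratio per pair); (2) per-group unit times — count, share of
episodes, total person-minutes, share of person-minutes, mean with t-based
95% CI (flagged degenerate below two observations), median and quartiles by
linear interpolation between order statistics (type 7, the numpy default;
the emulated forms state no rule); (3) per-day rates — households/day and
patients/day are means of per-day counts (not ratios of period totals,
which disagree with the published 9.5 households/day), while minutes per
patient and patients per household are ratios of period totals; (4) failure
reasons as counts, shares of all attempts, and per-month averages; (5)
bi-monthly bins (consecutive 2-calendar-month windows from the earliest
form date) of episode counts and median durations; (6) the TB / non-TB /
both composition of successful visits.

Between-clinic contrasts: the difference in medians uses a seeded
percentile bootstrap (default 2,000 resamples) rather than
quantile-regression asymptotics — distribution-free and exactly
reproducible; only the point estimate is comparable across methods. The
difference in means uses the Welch unequal-variance interval, numerically
the same as a robust-SE group-indicator regression for two groups.

## Costing

Health-system perspective. Register items are recurrent (annual ZAR
amounts) or capital (purchase price, life 2–5 years). Annualization default
is straight-line (`price / L`); an `annuitized` mode applies the standard
equivalent-annual-cost factor `r / (1 − (1+r)^−L)` at the configured
discount rate (default 5%/yr) and collapses to straight-line as `r → 0`.
Straight-line is the default because re-annuitizing a level stream at the
same rate returns `price / L`, which is what the emulated cost table uses.

Money is exact `Decimal` end to end; ZAR→USD conversion (1 USD = 14.448
ZAR, World Bank 2019) happens once, after aggregation, so no per-item
rounding drift accrues; presentation rounds to the cent. Assumptions: 250
working days/year, 8 h/day, of which 235 field minutes/day (the observed
average across both clinics). Derived columns: daily = annual/250;
field-day = daily × 235/480; per-pair = annual/pairs. Shared items (e.g.
office space) split equally between clinics by default, or proportionally
to observed person-minutes by option.

Top-down: cost per minute = annual/(250×8×60); per activity = per-minute ×
mean duration; per pair-day = annual/(pairs×250); per successful visit =
per-pair-day ÷ mean successful visits per pair-day. Bottom-up: staff costs
split equally across a clinic's pairs (salaries attach to people); all
other costs apportion proportionally to each pair's observed
person-minutes, quantized to a hundredth of a cent with the residual
assigned to the first pair so pair costs sum to the clinic total exactly.
A pair with no observed minutes is flagged and receives no apportioned
share. The per-visit denominator annualizes the observed visit rate (mean
successful visits per pair-day × pairs × 250); published per-visit figures
built on unpublished apportionment detail are not comparable and are not
asserted anywhere.

The economies-of-scale curve is `cost_per_pair_day / v` over visits/day
`v ≥ 1`: strictly decreasing and convex, so each additional visit saves
less than the one before, and the gap between a cheap and an expensive
clinic narrows as volume grows.

## Numerical and testing choices

- Seeds: every stochastic component (generator, bootstrap) takes an
  explicit seed; identical inputs give byte-identical outputs, including
  the CSV serialization (fixed row order by pair, date, start).
- Monte-Carlo checks run at ~700–825 clean pair-days (7+4 pairs × 75–100
  days), enough to hold binomial recovery of the success probabilities
  within 3 standard errors and the travel medians within bootstrap error,
  while the full suite stays in seconds.
- Degenerate inputs: empty groups report NaN statistics rather than
  raising; a single observation flags a degenerate CI; zero patients flag
  minutes-per-patient as undefined; constant samples flag the mean
  contrast as degenerate.
- Percentages and minutes are rounded to one decimal at presentation only.

## Known limitations

Travel is a marginal distribution, not a route model, so travel-time
*variance within a day* is unrealistic even though the per-episode
distribution is calibrated. The bottom-up/top-down distinction collapses
when pairs have similar observed minutes (both then equal annual ÷
pair-days); differences only emerge under pair heterogeneity the default
generator does not create. Sample medians of integer-minute durations move
in whole-minute steps, so median-based contrasts at field-study sizes
(~100 pair-days) jitter by ±1 minute; the acceptance script uses a larger
synthetic run for those quantities.
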