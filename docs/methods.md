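# Methods

This package implements a registry-based epidemiological pipeline for
amyotrophic lateral sclerosis (ALS): estimation of age/sex-specific
incidence and point prevalence from clinic case registers, Kaplan–Meier
estimation of disease duration, and century-scale projection of prevalent
cases under demographic change and hypothetical treatment scenarios.

## Case selection and counting

A registry row carries demographics, the onset/diagnosis/death-or-censor
dates, a motor neuron disease diagnosis label, an El Escorial certainty
category, and a postcode-sector identifier. Exclusions are applied in a
fixed order so audits are reproducible:

1. **diagnosis** — Kennedy's disease, unspecified lower motor neuron
   syndromes, and other non-MND diagnoses are dropped. ALS (all El
   Escorial categories, including "suspected" and missing), PLS, PMA and
   pure pseudobulbar palsy are kept.
2. **missing age at diagnosis** — required for band assignment.
3. **missing onset date** — survival analyses only, since duration is
   measured from symptom onset.

The audit tallies plus the kept count always equal the input count, and
the engine is idempotent. Records with a missing end-event are treated as
censored at the end date.

Kept incident cases are weighted by the fraction of their postcode sector
inside the study catchment (whole persons where the register is defined
by postcode criteria), then binned by sex and age at diagnosis into
sixteen 5-year bands from 15–19 to 85–89 plus an open 90+ band. Under-15s
are outside the scheme (adult-onset disease). Cells left at exactly zero
are set to 0.5 so that every cell yields a finite rate for
standardization and projection; positive fractional counts below 0.5 are
left untouched, and the substitution is re-evaluated after pooling two
regions so that real cases in one region rescue the other's empty cells.
Crude rates, by contrast, use the observed (pre-substitution) weighted
count — the substitution is a cell-level extrapolation device, not extra
observed cases.

## Rates and intervals

- Cell rates are `count / (mid-period population × study length)` per
  100,000 person-years; the default study length is 14 years (2004–2017)
  against a single census-year denominator.
- Confidence intervals for event counts use the exact (Garwood) Poisson
  interval via the chi-square formulation `low = χ²(α/2, 2k)/2`,
  `high = χ²(1−α/2, 2k+2)/2`, which extends continuously to the
  fractional counts produced by sector weighting and substitution. The
  exact interval is conservative by construction: realized coverage sits
  somewhat above the nominal 95%, which is what the replicate-coverage
  test asserts.
- Direct standardization weights cell rates by an external standard
  population; the overall rate weights each sex's cells by that sex's own
  standard counts. A standardized rate's CI treats the per-100,000 rate
  as a binomial proportion with the standard's total as denominator
  (`se = √(p(1−p)/N)`); this is one defensible reading of a
  textbook-level "binomial approximation" and is documented as such
  rather than claimed canonical.
- The standardized rate ratio between two regions uses a log-normal CI
  with `Var(log ratio) ≈ (se₁/r₁)² + (se₂/r₂)²`, the SEs recovered from
  the rates' interval widths.
- Point prevalence is `alive-on-the-date / population × 100,000` with a
  Wilson score interval.

## Disease duration

Duration runs from symptom onset to death or last follow-up in whole
months (floored, minimum one month, since medians are reported in integer
months). The product-limit estimator is implemented in-package with the
events-before-censorings tie convention; Greenwood variance accumulates
alongside. The median is the first event time with S(t) ≤ 0.5, its CI the
Brookmeyer–Crowley confidence set under the log(−log S) transform, and
the median SE is reported as the CI width over 2z. The restricted mean is
the area under S up to the largest event time with the standard
Greenwood-based area variance. Estimates are produced for three age
cohorts — under 40, 40–79 (following the reporting-table convention where
the cohort description is ambiguous between 40 and 41), and 80+ — keyed
on age at diagnosis, plus overall. An established survival library
(lifelines) serves as an independent oracle in the tests only.

## Prevalence projection and scenarios

Incident cases in a future year are the fixed age/sex-specific rates
applied to that year's projected population (constant-incidence
assumption; the only supported mode). Prevalent cases per stratum are

    rate / 100,000 × population × median duration (years),

with each 5-year band drawing its median from its duration cohort
(15–39 → <40, 40–79 → 40–79, 80+ bands → 80+), and per-100,000 prevalence
divides by the full all-age projected population.

Treatment scenarios transform duration only:

- **add_months(Δ)** — a Riluzole-equivalent gain of Δ = 3 months for all
  patients. Default basis scales every cohort by
  `(overall median + Δ) / overall median` (37/34 with the 34-month
  overall median), which is the arithmetic consistent with the published
  2020 scenario column; a per-cohort `median + Δ` variant is available
  via `add_months_basis="per_cohort"`.
- **multiply(m) over fraction f** — a gene therapy multiplying the
  carriers' median by m. The population-mean multiplier is
  `1 − f + f·m`, identical across cohorts (1.02 for the 4% *SOD1*
  fraction, 1.05 for the 10% *C9orf72* fraction at m = 1.5). A
  microsimulation averaging per-case subgroup durations confirms this
  closed form in the tests.
- **life_table over fraction f** — progression halted: the affected 10%
  survive to the period life expectancy at their band's representative
  age (band midpoint; 92 for 90+), sex, and calendar year, looked up in
  the projection year itself with no extrapolation beyond the table's
  horizon (2066).

## Synthetic data

The real inputs (clinic registers, national mid-year estimates,
projections, life tables) cannot be redistributed, so a seeded generator
produces structurally faithful stand-ins: an incidence surface
proportional to an age shape peaking at 75–84 with a 1.17 male:female
ratio; exponential (optionally Weibull) survival with cohort medians
(56, 35, 26 months); independent exponential censoring tuned so the
censored fraction is exactly the configured 15% (an administrative
fixed-date mode is also available); planted records triggering each
exclusion rule in the counts the flowchart checks expect; and region
presets whose sizes, sector-weight plans and denominators make the
synthetic crude rates land on the published values (152 raw cases →
122.9 weighted; 269 → 264 kept; 953 → 902 kept). Regional age pyramids
differ (young inner-city vs older suburban/rural), so standardization
lifts the urban rate above its crude value and the synthetic standardized
rates and rate ratio fall near the published ones without being pinned.

The UK-scale projection covers single-year ages 0–100 for 2020–2116 with
annual growth concentrated in the 80+ ages (so the oldest cohorts grow
severalfold by 2116). Its 2020 level is calibrated: given a rate surface
and cohort medians, the adult population is scaled so the 2020 incident
total is 1,701 and the under-15 padding sets the all-age denominator so
baseline 2020 prevalence is 8.58 per 100,000. Both anchors are only
jointly feasible for a sufficiently high rate surface (the default
`base_rate = 3.6`); with the rates actually estimated from the small
synthetic registries, 1,701 incident cases times a ~34-month median over
a UK-scale population implies a baseline nearer 7 per 100,000, so the
analysis driver calibrates on the incident total only and reports the
implied baseline. The published headline projections depend on the real
national projection data and are therefore checked for direction and
monotonicity, not value.

What passing tests do **not** show about real data: the generator shares
one incidence shape across regions, uses exponential survival, ignores
migration, ethnicity and cohort effects, and its demography is a
calibration device rather than a forecast. Tests demonstrate estimator
correctness and pipeline plumbing, not epidemiological truth.

## Numerical conventions

- Rounding is half-up to 2 decimal places, applied only at presentation;
  internal computation is full precision. Worked-example comparisons use
  ±0.01.
- Ties between events and censorings at the same time: events first.
- An undefined median (curve never reaching 0.5) is a flagged NaN, not an
  error; cohorts with fewer than two subjects are flagged.
- Zero population cells in a denominator are errors naming the cell;
  empty case sets after exclusion are legal.
- Problem sizes in the default test run: 500 replicate registries
  (~250 cases each) for CI coverage, 200 random samples for the
  product-limit oracle equivalence, 20 seeds of n = 900 for median
  recovery, 10⁵ simulated cases for the scenario microsimulation.
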