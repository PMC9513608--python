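# Methods

## Overview

`breadsalt` models the mortality impact of legal limits on the salt
content of bread. The pipeline has three stages:

1. **Market decomposition** (`bread_market`). Annual bread consumption
   is split into imported pre-packaged, national pre-packaged, and
   loose bakery bread. Imported bread plus the "traditional" fraction
   of national production is exempt from the statutory salt limit; the
   rest is regulated.
2. **Counterfactual intake shift** (`bread_market`,
   `uncertainty_scenarios`). Per-segment salt densities (g salt per
   100 g bread) are calibrated so their tonnage-weighted mean matches
   the density implied by dietary-survey data. A scenario caps
   in-scope segments at a legal threshold; the drop in mean density,
   scaled by per-capita bread consumption, is the per-capita salt
   reduction.
3. **Comparative risk assessment** (`cra_mortality`). For each
   age-band × sex stratum and each of seven salt-related
   cardiovascular causes, a potential impact fraction
   `PIF = 1 − E_cf[RR]/E_base[RR]` converts the intake shift into
   deaths averted (`deaths × PIF`), summed over strata and causes.
   Monte Carlo resampling of the dose–response slopes
   (`uncertainty_scenarios`) yields percentile confidence intervals.

The model is a single-baseline-year counterfactual: it asks how many
of the deaths observed in the baseline year would not have occurred
had the intake distribution been shifted. Morbidity, incidence,
time-lagged effects and consumer substitution are out of scope.

## Market calibration

Per-segment salt contents are not observed, so the calibration closes
an accounting identity. The regulated segment is split into a
compliant part at the voluntary-target density (default 1.0 g/100 g,
weight = compliance fraction) and a non-compliant part at the
statutory maximum (default 1.4 g/100 g). The exempt segment's density
is the free parameter solved so that the tonnage-weighted mean equals
the survey-implied market density

    density = bread_share_of_salt × salt_intake / bread_intake × 100.

With the default Portuguese constants (18.2% share, 7.4 g/day salt,
100.3 g/day bread) the implied mean is 1.343 g/100 g and the solved
exempt density is 1.61 g/100 g. The closure reproduces the target
mean to 1e-9 by construction; a solution below 0 or above
10 g/100 g raises a calibration error. Both fixed densities are
configurable; the defaults encode the Portuguese voluntary target and
statutory limit.

A scenario reduction uses the per-capita consumption basis: the
drop in mean density times per-capita bread intake gives g/person/day,
and national tonnes/day follow from the population. Published trade
and survey totals need not agree exactly (the pinned market total of
376,218 t/yr sits ~0.3% below the intake-derived 377,336 t/yr); a
pinned total that diverges by more than 1% from the intake-derived
total triggers a warning rather than an error.

## Dose–response model

Relative risk is log-linear in salt intake, either directly
(`beta` = log-RR per g/day) or mediated through systolic blood
pressure (`sbp_slope` in mmHg per g/day composed with `beta_sbp` in
log-RR per mmHg; the effective slope is their product). Entries may
carry age/sex qualifiers; the most specific matching entry applies to
a stratum, and a stratum cause with no matching entry is a
configuration error, never silently zero.

The packaged default file (`data/dose_response_default.csv`) uses the
blood-pressure pathway for all seven causes, with a salt→SBP slope of
1.0 mmHg per g/day and per-mmHg log-RRs in the range 0.010
(pulmonary embolism, rheumatic heart disease) to 0.050 (hypertensive
disease), assembled from the magnitude of trial meta-analyses of
sodium reduction and prospective pooling of SBP–CVD associations.
These defaults set plausible magnitudes for worked examples and the
headline recomputation; they are not a validated parameterisation,
and no test depends on their specific values — tests use synthetic
parameters with known truth. Standard errors are on the effective
(per g/day) slope scale, which is also the scale the Monte Carlo
sampler perturbs.

## Exposure distributions and quadrature

The default exposure family is a point mass at the population mean:
scenarios shift mean intake only, so the deterministic result equals
the closed form `deaths × (1 − exp(β·Δ))`, which every numerical path
is tested against. A normal family (truncated at zero and
renormalised) is provided for distributional fidelity; its
expectations use probabilists' Gauss–Hermite quadrature (order 64,
configurable), which matches the log-normal-mean closed form
`exp(β(μ−ref) + β²σ²/2)` within 1e-6 relative for |β|σ ≤ 1 in the
untruncated case. Truncation is numerically negligible in the
realistic intake regime (mean ≈ 7 g/day, sd ≈ 1–2 g/day) and is
asserted so by test.

Age bands are 5-year intervals from 0 to an open 85+ band. The
premature-mortality aggregate ("under 75") includes bands whose upper
bound is at most 75; the open terminal band is never premature.
Old-age attenuation of relative risks is not applied by default; the
age/sex qualifiers on dose–response entries are the hook for it.

## Monte Carlo uncertainty

Parameter uncertainty enters through the dose–response slopes only:
each effective slope is drawn independently from a normal with mean
the point estimate and sd its standard error (10,000 draws by
default; the seed is mandatory). Demographic and market inputs are
treated as fixed and explored through discrete sensitivity scenarios
instead. The central estimate is always the point-parameter value, so
it is invariant to the seed and the number of draws; the confidence
interval is the empirical 2.5th/97.5th percentile of total deaths
averted across draws, with linear interpolation between order
statistics (the interval endpoints depend on this convention, so it
is fixed and documented). With all standard errors zero the interval
collapses onto the central estimate exactly. Within a battery each
scenario consumes an independent seed stream spawned from the
configured seed, making the whole table reproducible bit for bit.

## Scenario battery

A scenario row bundles the legal threshold and scope with intake-side
sensitivity knobs:

- `compliance_fraction` re-runs the market calibration (altering the
  exempt-segment closure) before computing the reduction;
- `baseline_salt_g_day` / `baseline_scale` change the baseline intake
  first, which rescales the implied bread-salt density and hence the
  reduction proportionally (this is why a 10.7 g/day urinary-sodium
  baseline roughly triples the reduction);
- `bread_share_adjustment_g_day` adds a signed per-capita amount to
  the computed reduction. Moving bread's share of salt intake by ±1
  percentage point is operationalised as ±0.01 × baseline intake
  (±0.074 g/day at the 7.4 g baseline); the alternative reading —
  recalibrating the market at a 19.2%/17.2% share — changes the
  reduction by the compliance-weighted capped fraction of that amount
  and can be expressed through an explicit config row if wanted;
- `reduction_t_day_override` bypasses the market model and converts a
  stated national tonnes/day figure, for replaying published
  reductions.

The built-in battery (`synthetic_data.paper_fixture`) holds the two
counterfactual thresholds (extend 1.4 g/100 g to all bread; apply
1.0 g/100 g to all bread) and the ten published sensitivity rows.
Under the calibration above the universal 1.0 g cap yields a
reduction of 0.344 g/person/day (3.54 t/day nationally); the
extension of the 1.4 g cap yields 0.10 g/person/day. The published
analysis reports 0.35/3.6 and 0.13/1.4 for the same scenarios from
unprinted internal attributions; the first pair agrees within
rounding, the second does not, and since no printed attribution
reproduces it, the package reports its own calibrated value rather
than tuning toward the published one (the override hook exists for
exact replay).

## Synthetic data

`synthetic_data.generate_strata` emulates the structure of national
population/mortality tables: 18 age bands × 2 sexes, a population
pyramid that plateaus through working ages and contracts at older
ages with a female surplus at high ages, and cause-specific deaths
following a Gompertz-like exponential age gradient (log-slope
0.095/year, male excess risk ×1.4 at equal age). Expected counts are
normalised so each cause's national total matches a magnitude typical
of a mid-size Western European country (~27,000 deaths/year across
the seven causes at scale 1), then realised as seeded
negative-binomial draws (size 50, mild overdispersion). Only the
qualitative shape is emulated: passing tests demonstrate pipeline
correctness and invariance properties, not calibration to any real
population, and no test depends on specific generated counts beyond
invariants. Populations are rounded to whole persons so tables
round-trip losslessly through CSV.

## Numerical conventions

- Year length 365.25 days; tonne = 1e6 g; internal computation in
  grams/day at full floating precision, with rounding (intakes to two
  decimals, deaths to integers) applied only in the report layer.
- Per-capita conversions use the published population of 10,300,000.
- Monotonicity, conservation, idempotence and round-trip properties
  are enforced by property-based tests (seeded Hypothesis profiles).

## Problem sizes

Default runs are deliberately small: the market model is closed-form
arithmetic; the CRA evaluates 36 strata × 7 causes; Monte Carlo uses
10,000 draws per scenario and the coverage check uses 200 replicates
of 1,000 draws. The full battery with confidence intervals completes
in a few seconds on one core.

## Known limitations

- Per-segment salt densities are identified only through the closure;
  different attributions consistent with the same mean produce
  different scenario reductions (the dominant structural uncertainty
  on the market side).
- The default dose–response file is an order-of-magnitude
  parameterisation, not a systematic evidence synthesis; serious use
  should supply cause-specific slopes with provenance.
- Slope draws are independent across causes; correlated uncertainty
  (e.g. a shared SBP-mediation component) would widen intervals.
- Deaths only: no morbidity, no incidence, no multi-year projection,
  no substitution toward other salty foods.
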