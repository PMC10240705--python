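# Methods

## Model structure and assumptions

The package implements a deterministic, prevalence-based budget-impact
model of a digital inhaler-monitoring platform for COPD. Its structural
assumptions, chosen to match the published cohort model it re-implements:

* The eligible population (members ≥ 40 with COPD) is constant over the
  3-year horizon — no incidence, mortality or disenrollment.
* Uptake (10/15/30% by default) enrolls patients for the entirety of each
  year; there is no mid-year entry or half-cycle correction.
* COPD severity is carried by GOLD 2017 ABCD group membership only; HCRU
  rates, SABA use, controller mix and PDC differ by group, not by age.
* Monitoring reduces only hospitalizations, ED visits and SABA use.
  Office/outpatient visits and controller use are unchanged in the base
  case; every enrolled patient generates monitoring claims.
* Readmissions are a subset of the hospitalization rate and are not
  independently costed (`readmission_policy="subset"`); a
  `separately_costed` policy exists for exploration.
* No discounting over the horizon.

## Parameters

All inputs live in YAML configs validated by a strict schema
(`src/copd_bia/configs/schema.json`; unknown keys are errors so misspelled
parameters cannot silently disappear). The important tunables:

| parameter | unit | default | note |
|---|---|---|---|
| `plan_size` | members | 5,000,000 | payer plan |
| `prevalence` | fraction | 0.076 / 0.132 | COPD, 40–64 / ≥65 |
| `gold_distribution` | fraction | .534/.267/.082/.117 | A/B/C/D |
| `unit_costs` | 2020 USD/event | 126 / 3,065 / 25,839 | office / ED / hospitalization, commercial |
| `payment_ratios` | — | 1.43 / 2.64 / 1.89 | commercial→Medicare: office, ED/hosp-outpatient, inpatient |
| `saba.weekly_puffs` | puffs/week | 5.81/8.82/5.81/12.78 | by GOLD group |
| `controller.pdc` | fraction | .54/.60/.56/.62 | proportion of days covered |
| `effects` | fraction | hosp .30, ED .55, SABA .594 | monitoring effect sizes |
| `effects.subscription_cost` | USD/patient-yr | 200 | platform fee |
| `rtm` | — | 1×19.38 + 6×55.72 + 6×50.18 | CPT 98975/98976/98980 |
| `settings.days_per_year` | days | 365.25 | see below |
| `uptake` | fraction/yr | .10/.15/.30 | market penetration |

`days_per_year = 365.25` because the controller-cost pipeline then
reproduces the published $3,042/patient-year exactly (365 gives $3,040);
365 remains configurable. The weekly SABA row is parsed with GOLD A and C
sharing the low-symptom rate (5.81 puffs/week), consistent with the CAT
band mapping that generated it.

Medicare unit costs are derived by dividing the commercial costs by the
payment ratios and kept unrounded internally (office 88.11, ED 1,160.98,
hospitalization 13,671.43); the published table prints their rounded
forms.

### Derived vs replication configurations

The `*_derived` configs compute all baselines from the inputs above. The
GOLD-weighted hospitalization and ED rates they imply (0.4265 and
0.15325/patient-year) price the commercial baselines at $11,020 and $470 —
not the published $9,918 and $462, whose upstream weighting (possibly
age-stratified) is not recoverable. The `*_replication` configs therefore
override the hospitalization, ED and SABA baselines with the published
per-patient dollars ($9,918/$462/$292 commercial; $5,248/$175/$292
Medicare) via `baseline_cost_overrides` and `saba.annual_cost_override`.
They also carry an explicit `reconciliation_line` ($73 commercial, $74
Medicare) on the monitored arm: the published monitored-arm totals exceed
their own column sums by that amount, and the gap is carried as its own
labelled category rather than silently absorbed. The reconciliation line
is treated as a base-case bookkeeping artifact: alternative scenarios and
the break-even solvers exclude it (the base-case scenario spec keeps it so
that it reproduces the base impact table).

## Numerical conventions

* All internal arithmetic is unrounded; rounding happens exactly once, at
  render time, half away from zero ("half-up", matching every checkable
  published cell: 6,943; 208; 119; 655; 1,161; 13,671). Whole dollars for
  per-patient tables, 2 decimals for PMPM, 1 decimal of millions for
  aggregate expenditures. Rendered category sums may differ from a
  rendered total by ~$1; the JSON outputs carry unrounded doubles.
* The across-year average PMPM is the unweighted mean of the unrounded
  yearly values.
* Distribution validation (age shares, GOLD shares, controller mixes)
  rejects sums more than 1e-6 from 1; PDC shifted in scenarios is clipped
  to [0, 1].
* Break-even solutions use the closed form of a linear model and are
  cross-checked against an independent `brentq` bracketing solve
  (agreement within 1e-9; residual of the full cost difference below
  1e-6).

## The synthetic cohort

`simulate_cohort` draws, per patient: GOLD group (categorical), event
counts (Poisson at the deterministic annual rates, with the monitored
arm's reductions applied), SABA puffs (Poisson on the annual rate),
controller regimen (categorical from the group mix) and days covered
(Binomial(365, PDC), rescaled by 365.25/365 so the expectation equals
PDC × days_per_year exactly). Costs use the same unit costs and fees as
the deterministic engine, so every category mean is an unbiased estimator
of the deterministic per-patient cost; Poisson/Binomial are
minimal-assumption choices that affect variance only. When a config
carries a dollar baseline override, every per-group event rate is scaled
by a common factor so the simulated mean matches the override while
preserving GOLD structure; an overridden SABA cost enters as a
deterministic per-patient amount.

What the simulator emulates — and what it does not: it realizes the
cohort model's expectations with independent event types, fixed unit
costs, and no within-patient dynamics, comorbidity structure or
correlation between utilization categories. Agreement between simulator
and engine therefore validates the cohort arithmetic, not the model's
fidelity to real claims data.

The validation criterion is per-category agreement within 3 standard
errors at n = 100,000. Note that the *maximum* |z| over the ~40 stochastic
category/arm/config combinations checked by `scripts/acceptance.py` has an
expected value near 2.8 even for a perfectly unbiased simulator, so
isolated values slightly above 3 at some seeds are consistent with
agreement; the test suite uses fixed seeds and per-category checks.

`random_inputs` perturbs the commercial inputs multiplicatively (bounded
by 10× the published values), renormalizes all distributions and returns
parameter sets that are valid by construction — used to property-test the
engine away from the published corner of parameter space.

## Design choices where the design was open

* **Strict configs over warnings.** Unknown keys and any invariant
  violation are hard errors, and every violation is reported at once.
* **SABA per-puff pricing** uses a simple unweighted mean of the listed
  WAC canister prices over a single configurable actuations-per-canister
  (default 200); claims-weighted WAC averaging was not available to the
  original analysis either. The replication configs bypass this with the
  published $292.
* **Persistence linkage is exactly linear**: 0.10 PDC ↔ 5.20%/1.15%
  hospitalization/ED reductions, scaled proportionally (the 0.30 scenario
  uses exactly 3×), and extrapolated linearly in the budget-neutrality
  solver.
* **Problem sizes**: microsimulation runs use 100,000 patients per
  arm/config, which puts standard errors near $50 on a ~$14,000 total —
  small enough to detect any real arithmetic error while keeping the whole
  validation under a few seconds.

## Known limitations and divergences

* The published break-even values (5.04855% commercial, 12.547% Medicare)
  and budget-neutral PDC increases (14.16 / 27.03 points) are not
  reproducible from any combination of the published inputs under this
  linear model; the package reports its own solved values (4.3076% /
  11.1487%; 13.08 / 24.78 points) with machine-zero residuals and does not
  hard-code the published ones.
* The published ±10%/±25% sensitivity endpoints are mutually inconsistent
  with a linear model anchored at the published baselines: the sweep step
  is fixed at $322.95 per 10% by the published values 9,918 / 462 / 30% /
  55%, and no base saving renders all four published endpoints
  (2,152/2,797 and 1,668/3,282) simultaneously. The pipeline's base saving
  of $2,475.17 (which matches the published per-patient saving and every
  PMPM cell) renders 2,152 / 2,798 and 1,668 / 3,283 — the upper ends sit
  $1 above the published figures.
* The published 3-year net savings ($288.8M / $305.6M) differ by ~0.1%
  from the values implied by the published per-patient differences; the
  pipeline reports $288.9M / $305.4M.
* The Medicare monitored-arm hospitalization cell prints 3,673 in the
  source table while the published baseline override $5,248 implies
  3,673.6 → 3,674; the source's unrounded internal baseline evidently sat
  just below the printed value.
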