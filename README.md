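# copd-bia

Budget-impact analysis (BIA) of a digital inhaler-monitoring platform for
chronic obstructive pulmonary disease (COPD), from the perspectives of a
commercial payer and a Medicare fee-for-service payer. The package is
aimed at health-economics analysts who need a tested, scriptable
re-implementation of this class of spreadsheet cohort model: every input
is a validated config file, every table is reproducible from the command
line, and the deterministic arithmetic is validated against an independent
patient-level microsimulation.

## The model

A prevalence-based cohort model over a 3-year horizon with no discounting.
For a plan of *N* members with age-band shares *s_a* and COPD prevalence
*p_a* (members under 40 are excluded), the eligible population is

    E = N × Σ_a s_a p_a ,        a ∈ {40–64, ≥65}

Patients fall into GOLD 2017 ABCD groups with shares *w_g*. Annual
per-patient baseline cost is built per category and GOLD-weighted:

* medical: Σ_g w_g (rate_g × unit cost) for office/outpatient visits, ED
  visits and hospitalizations (readmissions are a subset of
  hospitalizations and add nothing by default);
* rescue inhaler (SABA): weekly puffs_g × weeks/year × (mean WAC canister
  price / actuations per canister);
* controller medication: Σ_g w_g (mix-weighted daily cost_g) × PDC_g ×
  days/year, where PDC is the proportion of days covered.

The monitored arm pays a subscription (USD 200/patient-year) and a
remote-therapeutic-monitoring fee schedule (CPT 98975/98976/98980,
$654.78/patient-year), while hospitalizations fall 30%, ED visits 55% and
SABA use 59.4%. With uptake *u_y* (10/15/30%), the budget impact in year
*y* is expressed per member per month:

    PMPM_y = (C_enrolled − C_unenrolled) × u_y E / (12 N)

On top of the base case the package provides persistence-linked
alternative scenarios (a +0.10 PDC increase linked to 5.20%/1.15%
hospitalization/ED reductions, and 3× that), one-way ±10%/±25% sensitivity
sweeps, closed-form break-even solvers (verified by bisection), and a
seeded Monte-Carlo cohort simulator whose expectation equals the
deterministic model.

Two configurations ship per payer: `*_derived` computes every baseline
from the published input table, while `*_replication` substitutes the
published per-patient hospitalization/ED/SABA dollar baselines (their
upstream derivation is not recoverable from the inputs alone) and carries
an explicit reconciliation line on the monitored arm.

## Worked example

```
$ bia run --config commercial_replication --out results/run
eligible COPD patients: 212,200
per-patient saving: 2,475 USD/patient-year
average PMPM impact: -1.60
outputs written to results/run
```

A 5-million-member commercial plan contains 212,200 eligible COPD
patients. Monitoring saves $2,475 per enrolled patient per year (the
unenrolled arm costs $14,047, the monitored arm $11,572), and under the
10/15/30% uptake schedule the plan's budget impact averages −1.60 PMPM
over three years. The Medicare configuration gives 606,600 eligible
patients, a $915 per-patient saving and −1.70 PMPM. Other entry points:

```
$ bia breakeven --config commercial_replication
break-even hospitalization reduction: 4.3076% (residual 0.00e+00)
budget-neutral PDC increase: 13.08 percentage points (controller costs excluded)

$ bia scenario --config commercial_replication --spec 1A
$ bia sensitivity --config commercial_replication --param medical_unit_costs
$ bia simulate --config commercial_derived --n 100000 --seed 1 --arm enrolled
```

The numbered scripts under `analysis/` run the same pipeline end to end
(population → per-patient costs → PMPM → scenarios → sensitivity/break-even
→ microsimulation validation) and write their tables under `results/`.

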