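"""Patient-level Monte-Carlo simulator used as an independent oracle for
the deterministic cohort arithmetic, plus a randomized-parameter generator
for property tests.

Each simulated patient draws a GOLD group, Poisson event counts at the
deterministic model's annual rates (with the monitored arm's reductions
applied to hospitalizations, ED visits and SABA use), a controller regimen
from the group mix, and Binomial days-covered at the group PDC. Costs are
accumulated with exactly the same unit costs and fees as the deterministic
engine, so every category's expectation equals the deterministic
per-patient cost; the choice of Poisson/Binomial affects variance only.

Draw order (one seeded generator): GOLD group, outpatient visits, ED
visits, hospitalizations, SABA puffs, controller category, days covered.
Bit-compatibility across generator families is not promised — only
statistical equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from copd_bia.cost_engine import (
    annual_medical_costs,
    annual_rtm_cost,
    gold_weighted_mean,
    saba_cost_per_puff,
)
from copd_bia.parameters import (
    CONTROLLER_CATEGORIES,
    GOLD_GROUPS,
    PayerInputs,
    load_builtin,
)

ARMS = ("unenrolled", "enrolled")


@dataclass(frozen=True)
class SimSummary:
    """Monte-Carlo estimate of mean per-patient annual cost by category."""

    arm: str
    n: int
    seed: int
    means: dict  # category -> mean USD/patient-year
    standard_errors: dict  # category -> SE of the mean

    def z_score(self, category: str, deterministic_value: float) -> float:
        """Distance of the deterministic value from the simulated mean, in
        standard errors (0 when both are exactly zero)."""
        se = self.standard_errors[category]
        diff = self.means[category] - deterministic_value
        if se == 0.0:
            return 0.0 if diff == 0.0 else np.inf
        return diff / se


def _rate_scale(inputs: PayerInputs, kind: str) -> float:
    """Scale factor applied to per-GOLD event rates when a replication
    config carries a dollar baseline override: every group rate is scaled
    by override / (weighted rate x unit cost), preserving GOLD structure
    while matching the aggregate mean."""
    over = inputs.baseline_cost_overrides
    override = getattr(over, "hospitalizations" if kind == "hosp" else "ed_visits")
    if override is None:
        return 1.0
    med = annual_medical_costs(inputs.hcru, inputs.unit_costs, inputs.gold_distribution)
    derived = med["hospitalizations" if kind == "hosp" else "ed_visits"]
    if derived == 0.0:
        return 1.0
    return override / derived


def simulate_cohort(
    inputs: PayerInputs, n: int, seed: int, arm: str = "unenrolled"
) -> SimSummary:
    """Simulate ``n`` patients of one arm and summarize per-category costs.

    Identical (inputs, n, seed, arm) give identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}")
    rng = np.random.default_rng(seed)
    enrolled = arm == "enrolled"
    eff = inputs.effects
    settings = inputs.settings

    shares = np.asarray(inputs.gold_distribution.as_tuple(), dtype=float)
    group = rng.choice(len(GOLD_GROUPS), size=n, p=shares / shares.sum())

    out_rate = np.asarray(inputs.hcru.outpatient_visits.as_tuple())[group]
    ed_rate = np.asarray(inputs.hcru.ed_visits.as_tuple())[group] * _rate_scale(inputs, "ed")
    hosp_rate = np.asarray(inputs.hcru.hospitalizations.as_tuple())[group] * _rate_scale(
        inputs, "hosp"
    )
    if enrolled:
        ed_rate = ed_rate * (1.0 - eff.ed_reduction)
        hosp_rate = hosp_rate * (1.0 - eff.hosp_reduction)

    outpatient = rng.poisson(out_rate)
    ed = rng.poisson(ed_rate)
    hosp = rng.poisson(hosp_rate)

    uc = inputs.unit_costs
    cost = {
        "outpatient_office": outpatient * uc.office_outpatient_visit,
        "ed_visits": ed * uc.ed_visit,
        "hospitalizations": hosp * uc.hospitalization,
    }

    saba_factor = (1.0 - eff.saba_reduction) if enrolled else 1.0
    if inputs.saba.annual_cost_override is not None:
        cost["saba"] = np.full(n, inputs.saba.annual_cost_override * saba_factor)
        rng.poisson(np.zeros(n))  # keep the draw order identical across modes
    else:
        weekly = np.asarray(inputs.saba.weekly_puffs.as_tuple())[group]
        annual_puffs = weekly * settings.weeks_per_year * saba_factor
        puffs = rng.poisson(annual_puffs)
        per_puff = saba_cost_per_puff(inputs.saba) if np.any(annual_puffs > 0) else 0.0
        cost["saba"] = puffs * per_puff

    mix = np.array(
        [
            [inputs.controller.mix.for_group(g).as_dict()[c] for c in CONTROLLER_CATEGORIES]
            for g in GOLD_GROUPS
        ]
    )
    daily = np.asarray(
        [inputs.controller.daily_costs.as_dict()[c] for c in CONTROLLER_CATEGORIES]
    )
    # vectorized categorical draw per patient from the group's mix
    cum = np.cumsum(mix[group], axis=1)
    u = rng.random(n)
    category = (u[:, None] > cum).sum(axis=1).clip(max=len(CONTROLLER_CATEGORIES) - 1)
    pdc = np.asarray(inputs.controller.pdc.as_tuple())[group]
    n_days = int(round(settings.days_per_year))
    days = rng.binomial(n_days, pdc)
    # rescale so E[cost] = daily x PDC x days_per_year even when the year
    # length is not an integer
    cost["controller"] = daily[category] * days * (settings.days_per_year / n_days)

    if enrolled:
        cost["propeller"] = np.full(n, eff.subscription_cost)
        cost["rtm"] = np.full(
            n, annual_rtm_cost(inputs.rtm) if eff.bill_rtm_for_all_enrolled else 0.0
        )
        cost["reconciliation"] = np.full(n, settings.reconciliation_line)
    else:
        cost["propeller"] = np.zeros(n)
        cost["rtm"] = np.zeros(n)
        cost["reconciliation"] = np.zeros(n)

    total = sum(cost.values())
    cost["total"] = total
    means = {c: float(v.mean()) for c, v in cost.items()}
    ses = {c: float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0 for c, v in cost.items()}
    return SimSummary(arm=arm, n=n, seed=seed, means=means, standard_errors=ses)


def random_inputs(seed: int) -> PayerInputs:
    """Draw a valid random parameter set for property tests.

    The published commercial inputs are perturbed multiplicatively (bounded
    by 10x their values), distributions are renormalized to sum to one, and
    the result always passes validation.
    """
    rng = np.random.default_rng(seed)
    base = load_builtin("commercial_derived")

    def simplex(k):
        w = rng.uniform(0.05, 1.0, size=k)
        w = w / w.sum()
        # renormalize once more in float to keep the sum within 1e-9 of 1
        return [float(x) for x in w / w.sum()]

    def scale(x, lo=0.1, hi=10.0):
        return float(x * rng.uniform(lo, hi))

    age = simplex(3)
    gold = dict(zip(GOLD_GROUPS, simplex(4)))
    hosp = {g: scale(getattr(base.hcru.hospitalizations, g), 0.2, 3.0) for g in GOLD_GROUPS}
    readmit = {g: hosp[g] * rng.uniform(0.0, 0.5) for g in GOLD_GROUPS}
    mix = {g: dict(zip(CONTROLLER_CATEGORIES, simplex(5))) for g in GOLD_GROUPS}
    data = {
        "payer": "commercial",
        "population": {
            "plan_size": float(rng.uniform(1e5, 1e7)),
            "age_shares": {
                "under_40": age[0],
                "age_40_64": age[1],
                "age_65_plus": age[2],
            },
        },
        "prevalence": {
            "age_40_64": float(rng.uniform(0.0, 0.5)),
            "age_65_plus": float(rng.uniform(0.0, 0.5)),
        },
        "gold_distribution": gold,
        "hcru": {
            "outpatient_visits": {
                g: scale(getattr(base.hcru.outpatient_visits, g), 0.2, 3.0)
                for g in GOLD_GROUPS
            },
            "ed_visits": {
                g: scale(getattr(base.hcru.ed_visits, g), 0.2, 3.0) for g in GOLD_GROUPS
            },
            "hospitalizations": hosp,
            "readmissions": readmit,
        },
        "unit_costs": {
            "office_outpatient_visit": scale(base.unit_costs.office_outpatient_visit),
            "ed_visit": scale(base.unit_costs.ed_visit),
            "hospitalization": scale(base.unit_costs.hospitalization),
        },
        "saba": {
            "weekly_puffs": {
                g: scale(getattr(base.saba.weekly_puffs, g), 0.2, 3.0)
                for g in GOLD_GROUPS
            },
            "actuations_per_canister": int(rng.integers(50, 400)),
            "wac_prices": [
                {"label": f"product-{i}", "price": scale(p.price)}
                for i, p in enumerate(base.saba.wac_prices)
            ],
        },
        "controller": {
            "daily_costs": {
                c: scale(getattr(base.controller.daily_costs, c))
                for c in CONTROLLER_CATEGORIES
            },
            "mix": mix,
            "pdc": {g: float(rng.uniform(0.0, 1.0)) for g in GOLD_GROUPS},
        },
        "rtm": [
            {
                "code": e.code,
                "annual_frequency": int(rng.integers(0, 13)),
                "fee": scale(e.fee),
            }
            for e in base.rtm
        ],
        "effects": {
            "hosp_reduction": float(rng.uniform(0.0, 1.0)),
            "ed_reduction": float(rng.uniform(0.0, 1.0)),
            "saba_reduction": float(rng.uniform(0.0, 1.0)),
            "subscription_cost": scale(base.effects.subscription_cost),
            "bill_rtm_for_all_enrolled": bool(rng.integers(0, 2)),
        },
        "uptake": [float(rng.uniform(0.0, 1.0)) for _ in range(3)],
        "settings": {
            "days_per_year": 365.25,
            "reconciliation_line": float(rng.uniform(0.0, 100.0)),
        },
    }
    return PayerInputs.model_validate(data)
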