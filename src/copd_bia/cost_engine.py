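"""Per-patient annual cost breakdowns for the two arms.

The unenrolled (baseline) arm accrues GOLD-weighted medical costs
(outpatient/office, ED, hospitalizations), rescue-inhaler (SABA) cost and
PDC-weighted controller medication cost. The enrolled (monitored) arm
additionally pays the platform subscription and the remote-therapeutic-
monitoring (RTM) fee schedule, while hospitalization, ED and SABA costs are
scaled down by the intervention effect sizes; outpatient and controller
costs are unchanged in the base case.

All arithmetic here is unrounded; dollars are rounded half-up only at the
reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from copd_bia.parameters import (
    GOLD_GROUPS,
    ControllerInputs,
    GoldDistribution,
    HcruProfile,
    InterventionEffects,
    ModelSettings,
    PayerInputs,
    PerGold,
    RtmEntry,
    SabaInputs,
    UnitCostSet,
)

#: cost categories in report order ("propeller" is the platform subscription)
CATEGORIES = (
    "propeller",
    "hospitalizations",
    "ed_visits",
    "outpatient_office",
    "rtm",
    "saba",
    "controller",
    "reconciliation",
)

READMISSION_POLICIES = ("subset", "separately_costed")


@dataclass(frozen=True)
class CostBreakdown:
    """Per-patient annual cost by category (USD/patient-year) for one arm."""

    arm: str  # "unenrolled" | "enrolled"
    propeller: float = 0.0
    hospitalizations: float = 0.0
    ed_visits: float = 0.0
    outpatient_office: float = 0.0
    rtm: float = 0.0
    saba: float = 0.0
    controller: float = 0.0
    reconciliation: float = 0.0

    @property
    def total(self) -> float:
        return math.fsum(getattr(self, c) for c in CATEGORIES)

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in CATEGORIES}


def gold_weighted_mean(values, dist: GoldDistribution) -> float:
    """Weight one value per GOLD group by the group shares.

    ``values`` may be a :class:`PerGold`, a mapping keyed by group, or a
    sequence in ABCD order.
    """
    if isinstance(values, PerGold):
        seq = values.as_tuple()
    elif isinstance(values, dict):
        seq = tuple(values[g] for g in GOLD_GROUPS)
    else:
        seq = tuple(values)
    shares = dist.as_tuple()
    return math.fsum(s * v for s, v in zip(shares, seq))


def annual_medical_costs(
    hcru: HcruProfile,
    costs: UnitCostSet,
    dist: GoldDistribution,
    readmission_policy: str = "subset",
) -> dict[str, float]:
    """GOLD-weighted annual medical cost per patient, by category.

    Under the default ``subset`` policy readmissions are already contained
    in the hospitalization rate and add nothing; ``separately_costed`` adds
    the weighted readmission rate at the hospitalization unit cost.
    """
    if readmission_policy not in READMISSION_POLICIES:
        raise ValueError(
            f"unknown readmission policy {readmission_policy!r}; "
            f"choose from {READMISSION_POLICIES}"
        )
    outpatient = gold_weighted_mean(hcru.outpatient_visits, dist) * costs.office_outpatient_visit
    ed = gold_weighted_mean(hcru.ed_visits, dist) * costs.ed_visit
    hosp = gold_weighted_mean(hcru.hospitalizations, dist) * costs.hospitalization
    if readmission_policy == "separately_costed":
        hosp += gold_weighted_mean(hcru.readmissions, dist) * costs.hospitalization
    return {
        "outpatient_office": outpatient,
        "ed_visits": ed,
        "hospitalizations": hosp,
    }


def saba_cost_per_puff(saba: SabaInputs) -> float:
    """Simple (unweighted) mean of the listed WAC canister prices divided by
    actuations per canister."""
    if not saba.wac_prices:
        raise ValueError("SABA WAC price list is empty and no annual cost override set")
    mean_wac = math.fsum(p.price for p in saba.wac_prices) / len(saba.wac_prices)
    return mean_wac / saba.actuations_per_canister


def annual_saba_cost(
    saba: SabaInputs, dist: GoldDistribution, settings: ModelSettings
) -> float:
    """Annual rescue-inhaler cost per patient.

    If the config carries an annual cost override (replication mode) it is
    returned directly; otherwise GOLD-weighted weekly puffs x weeks/year x
    per-puff cost.
    """
    if saba.annual_cost_override is not None:
        return saba.annual_cost_override
    weekly = gold_weighted_mean(saba.weekly_puffs, dist)
    if weekly == 0.0:
        return 0.0
    return weekly * settings.weeks_per_year * saba_cost_per_puff(saba)


def controller_daily_cost(ctrl: ControllerInputs, group: str) -> float:
    """Mix-weighted controller cost per day for one GOLD group."""
    mix = ctrl.mix.for_group(group).as_dict()
    daily = ctrl.daily_costs.as_dict()
    return math.fsum(mix[c] * daily[c] for c in daily)


def annual_controller_cost(
    ctrl: ControllerInputs,
    dist: GoldDistribution,
    settings: ModelSettings,
    pdc_delta: float = 0.0,
) -> float:
    """GOLD-weighted annual controller medication cost per patient.

    Per group: (mix-weighted daily cost) x PDC x days/year, with the group
    PDC shifted by ``pdc_delta`` and clipped to [0, 1].
    """
    per_group = []
    for g in GOLD_GROUPS:
        pdc = min(max(getattr(ctrl.pdc, g) + pdc_delta, 0.0), 1.0)
        per_group.append(controller_daily_cost(ctrl, g) * pdc * settings.days_per_year)
    return gold_weighted_mean(per_group, dist)


def annual_rtm_cost(schedule: list[RtmEntry]) -> float:
    """Sum of billing frequency x fee over the RTM code schedule."""
    return math.fsum(e.annual_frequency * e.fee for e in schedule)


def baseline_breakdown(
    inputs: PayerInputs, readmission_policy: str = "subset"
) -> CostBreakdown:
    """Unenrolled-arm per-patient annual cost breakdown.

    Published dollar baselines in ``baseline_cost_overrides`` (replication
    configs) replace the corresponding rate-derived values.
    """
    med = annual_medical_costs(
        inputs.hcru, inputs.unit_costs, inputs.gold_distribution, readmission_policy
    )
    over = inputs.baseline_cost_overrides
    hosp = med["hospitalizations"] if over.hospitalizations is None else over.hospitalizations
    ed = med["ed_visits"] if over.ed_visits is None else over.ed_visits
    return CostBreakdown(
        arm="unenrolled",
        hospitalizations=hosp,
        ed_visits=ed,
        outpatient_office=med["outpatient_office"],
        saba=annual_saba_cost(inputs.saba, inputs.gold_distribution, inputs.settings),
        controller=annual_controller_cost(
            inputs.controller, inputs.gold_distribution, inputs.settings
        ),
    )


def enrolled_breakdown(
    base: CostBreakdown,
    effects: InterventionEffects,
    rtm: list[RtmEntry],
    settings: ModelSettings,
    *,
    include_reconciliation: bool = True,
    controller_addition: float = 0.0,
) -> CostBreakdown:
    """Monitored-arm breakdown built from the unenrolled baseline.

    Hospitalization, ED and SABA costs are scaled by (1 - reduction);
    outpatient and controller costs carry over (``controller_addition``
    supports scenarios that cost increased refill persistence); the platform
    subscription and, when billed, the RTM fee schedule are added; the
    configured reconciliation line is added unless excluded.
    """
    if base.arm != "unenrolled":
        raise ValueError("enrolled_breakdown expects an unenrolled baseline")
    return CostBreakdown(
        arm="enrolled",
        propeller=effects.subscription_cost,
        hospitalizations=base.hospitalizations * (1.0 - effects.hosp_reduction),
        ed_visits=base.ed_visits * (1.0 - effects.ed_reduction),
        outpatient_office=base.outpatient_office,
        rtm=annual_rtm_cost(rtm) if effects.bill_rtm_for_all_enrolled else 0.0,
        saba=base.saba * (1.0 - effects.saba_reduction),
        controller=base.controller + controller_addition,
        reconciliation=settings.reconciliation_line if include_reconciliation else 0.0,
    )


def arm_breakdowns(
    inputs: PayerInputs, readmission_policy: str = "subset"
) -> tuple[CostBreakdown, CostBreakdown]:
    """(unenrolled, enrolled) breakdowns for the base case."""
    base = baseline_breakdown(inputs, readmission_policy)
    return base, enrolled_breakdown(base, inputs.effects, inputs.rtm, inputs.settings)


def group_breakdowns(
    inputs: PayerInputs, readmission_policy: str = "subset"
) -> dict[str, tuple[CostBreakdown, CostBreakdown]]:
    """Per-GOLD-group (unenrolled, enrolled) breakdowns.

    Built by evaluating the engine on a degenerate GOLD distribution per
    group. Dollar baseline overrides are apportioned so that their
    GOLD-weighted mean reproduces the aggregate override: each group's
    rate-derived cost is scaled by a common factor.
    """
    out = {}
    over = inputs.baseline_cost_overrides
    agg = annual_medical_costs(
        inputs.hcru, inputs.unit_costs, inputs.gold_distribution, readmission_policy
    )
    for g in GOLD_GROUPS:
        dist = GoldDistribution(**{k: 1.0 if k == g else 0.0 for k in GOLD_GROUPS})
        med = annual_medical_costs(
            inputs.hcru, inputs.unit_costs, dist, readmission_policy
        )
        hosp = med["hospitalizations"]
        if over.hospitalizations is not None and agg["hospitalizations"] > 0:
            hosp *= over.hospitalizations / agg["hospitalizations"]
        ed = med["ed_visits"]
        if over.ed_visits is not None and agg["ed_visits"] > 0:
            ed *= over.ed_visits / agg["ed_visits"]
        base = CostBreakdown(
            arm="unenrolled",
            hospitalizations=hosp,
            ed_visits=ed,
            outpatient_office=med["outpatient_office"],
            saba=annual_saba_cost(inputs.saba, dist, inputs.settings),
            controller=annual_controller_cost(inputs.controller, dist, inputs.settings),
        )
        out[g] = (
            base,
            enrolled_breakdown(base, inputs.effects, inputs.rtm, inputs.settings),
        )
    return out
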