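"""Alternative scenarios, one-way sensitivity sweeps and break-even solvers.

The alternative scenarios replace the directly observed hospitalization/ED
reductions with smaller, persistence-linked ones (a 0.10 PDC increase is
linked to 5.20%/1.15% reductions in inpatient/ED use; a 0.30 increase to
three times that) and optionally cost the increased controller refill
persistence itself.

The model is linear in every effect size, so the break-even hospitalization
reduction and the budget-neutral PDC increase have closed forms; each is
cross-checked with an independent root bracketing solve on the full
per-patient cost difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy.optimize import brentq

from copd_bia.budget_impact import ExpenditureReport, PmpmSeries, aggregate_expenditures, pmpm_table
from copd_bia.cost_engine import (
    GOLD_GROUPS,
    CostBreakdown,
    annual_rtm_cost,
    baseline_breakdown,
    controller_daily_cost,
    enrolled_breakdown,
    gold_weighted_mean,
)
from copd_bia.parameters import (
    ControllerInputs,
    GoldDistribution,
    ModelSettings,
    PayerInputs,
)
from copd_bia.population import population_counts

SENSITIVITY_PARAMETERS = ("medical_unit_costs", "hcru_reductions", "saba_reduction")


@dataclass(frozen=True)
class ScenarioSpec:
    """Effect overrides for one scenario.

    ``None`` overrides fall back to the config's base-case effects. The
    reconciliation line is a base-case bookkeeping artifact and is excluded
    from the alternative scenarios.
    """

    label: str
    pdc_delta: float = 0.0
    hosp_reduction: Optional[float] = None
    ed_reduction: Optional[float] = None
    saba_reduction: Optional[float] = None
    include_controller_costs: bool = False
    include_reconciliation: bool = False

    def __post_init__(self):
        if not 0.0 <= self.pdc_delta <= 1.0:
            raise ValueError("pdc_delta must be in [0, 1]")
        for name in ("hosp_reduction", "ed_reduction", "saba_reduction"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


#: the published scenario set; "base" reproduces the base-case impact table
BUILTIN_SCENARIOS: dict[str, ScenarioSpec] = {
    "base": ScenarioSpec("base", include_reconciliation=True),
    "1A": ScenarioSpec("1A", 0.10, 0.052, 0.0115, include_controller_costs=True),
    "1B": ScenarioSpec("1B", 0.10, 0.052, 0.0115, include_controller_costs=False),
    "2A": ScenarioSpec("2A", 0.30, 0.156, 0.0345, include_controller_costs=True),
    "2B": ScenarioSpec("2B", 0.30, 0.156, 0.0345, include_controller_costs=False),
}


@dataclass(frozen=True)
class ScenarioResult:
    spec: ScenarioSpec
    impact: PmpmSeries
    expenditures: ExpenditureReport
    unenrolled: CostBreakdown
    enrolled: CostBreakdown

    @property
    def per_patient_difference(self) -> float:
        return self.enrolled.total - self.unenrolled.total


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    relative_changes: tuple[float, ...]
    savings: tuple[float, ...]  # per-patient annual saving at each change
    base_saving: float


@dataclass(frozen=True)
class BreakEvenResult:
    """Solved effect size at which the monitored arm's costs exactly offset
    its savings."""

    value: float  # hospitalization-reduction fraction, or PDC points
    residual: float  # per-patient cost difference at the solution
    out_of_range: bool = False
    bisection_value: Optional[float] = None


def pdc_cost_delta(
    ctrl: ControllerInputs,
    dist: GoldDistribution,
    pdc_delta: float,
    settings: ModelSettings,
) -> float:
    """Annual per-patient controller cost of a PDC increase.

    Per group: mix-weighted daily cost x effective PDC shift x days/year,
    with the shifted PDC clipped at 1; GOLD-weighted across groups.
    """
    if pdc_delta < 0:
        raise ValueError("pdc_delta must be >= 0")
    per_group = []
    for g in GOLD_GROUPS:
        pdc = getattr(ctrl.pdc, g)
        effective = min(pdc + pdc_delta, 1.0) - pdc
        per_group.append(controller_daily_cost(ctrl, g) * effective * settings.days_per_year)
    return gold_weighted_mean(per_group, dist)


def _effects_for(inputs: PayerInputs, spec: ScenarioSpec):
    updates = {}
    for name in ("hosp_reduction", "ed_reduction", "saba_reduction"):
        v = getattr(spec, name)
        if v is not None:
            updates[name] = v
    return inputs.effects.model_copy(update=updates) if updates else inputs.effects


def run_scenario(inputs: PayerInputs, spec: ScenarioSpec) -> ScenarioResult:
    """Rebuild the monitored arm under a scenario's effect overrides and
    return its impact PMPM series and expenditure report."""
    counts = population_counts(inputs)
    base = baseline_breakdown(inputs)
    addition = (
        pdc_cost_delta(
            inputs.controller, inputs.gold_distribution, spec.pdc_delta, inputs.settings
        )
        if spec.include_controller_costs
        else 0.0
    )
    enrolled = enrolled_breakdown(
        base,
        _effects_for(inputs, spec),
        inputs.rtm,
        inputs.settings,
        include_reconciliation=spec.include_reconciliation,
        controller_addition=addition,
    )
    tables = pmpm_table(base, enrolled, counts, inputs.plan_size)
    return ScenarioResult(
        spec=spec,
        impact=tables["impact"],
        expenditures=aggregate_expenditures(base, enrolled, counts),
        unenrolled=base,
        enrolled=enrolled,
    )


def _per_patient_saving(inputs: PayerInputs) -> float:
    base = baseline_breakdown(inputs)
    enrolled = enrolled_breakdown(base, inputs.effects, inputs.rtm, inputs.settings)
    return base.total - enrolled.total


def _scaled_inputs(inputs: PayerInputs, parameter: str, change: float) -> PayerInputs:
    k = 1.0 + change
    if parameter == "medical_unit_costs":
        uc = inputs.unit_costs.model_copy(
            update={
                "ed_visit": inputs.unit_costs.ed_visit * k,
                "hospitalization": inputs.unit_costs.hospitalization * k,
            }
        )
        over = inputs.baseline_cost_overrides
        over = over.model_copy(
            update={
                "hospitalizations": None
                if over.hospitalizations is None
                else over.hospitalizations * k,
                "ed_visits": None if over.ed_visits is None else over.ed_visits * k,
            }
        )
        # drop the derivation provenance so the scaled costs stand alone
        return inputs.model_copy(
            update={
                "unit_costs": uc,
                "baseline_cost_overrides": over,
                "commercial_unit_costs": None,
                "payment_ratios": None,
            }
        )
    if parameter == "hcru_reductions":
        eff = inputs.effects.model_copy(
            update={
                "hosp_reduction": min(max(inputs.effects.hosp_reduction * k, 0.0), 1.0),
                "ed_reduction": min(max(inputs.effects.ed_reduction * k, 0.0), 1.0),
            }
        )
        return inputs.model_copy(update={"effects": eff})
    if parameter == "saba_reduction":
        eff = inputs.effects.model_copy(
            update={"saba_reduction": min(max(inputs.effects.saba_reduction * k, 0.0), 1.0)}
        )
        return inputs.model_copy(update={"effects": eff})
    raise ValueError(
        f"unknown sensitivity parameter {parameter!r}; choose from {SENSITIVITY_PARAMETERS}"
    )


def one_way_sensitivity(
    inputs: PayerInputs, parameter: str, relative_changes: list[float]
) -> SensitivityResult:
    """Per-patient annual saving with one parameter scaled by (1 + change).

    The hospitalization and ED saving components are bilinear in the unit
    costs and in the effect sizes, so ``medical_unit_costs`` and
    ``hcru_reductions`` scale the saving identically.
    """
    savings = tuple(
        _per_patient_saving(_scaled_inputs(inputs, parameter, c))
        for c in relative_changes
    )
    return SensitivityResult(
        parameter=parameter,
        relative_changes=tuple(relative_changes),
        savings=savings,
        base_saving=_per_patient_saving(inputs),
    )


def _difference_at_hosp_reduction(inputs: PayerInputs, r: float, include_reconciliation: bool) -> float:
    base = baseline_breakdown(inputs)
    eff = inputs.effects.model_copy(update={"hosp_reduction": min(max(r, 0.0), 1.0)})
    # evaluate the linear extension outside [0, 1] explicitly for bracketing
    enrolled = enrolled_breakdown(
        base, eff.model_copy(update={"hosp_reduction": 0.0}), inputs.rtm, inputs.settings,
        include_reconciliation=include_reconciliation,
    )
    return (enrolled.total - r * base.hospitalizations) - base.total


def break_even_hosp_reduction(
    inputs: PayerInputs, *, include_reconciliation: bool = False
) -> BreakEvenResult:
    """Hospitalization-reduction fraction at which enrolled and unenrolled
    per-patient annual costs are equal.

    Closed form (the cost difference is linear in the reduction), verified
    with an independent bracketing root solve; the reconciliation line is a
    base-case bookkeeping artifact and is excluded by default.
    """
    base = baseline_breakdown(inputs)
    if base.hospitalizations <= 0:
        raise ValueError("baseline hospitalization cost must be positive")
    eff = inputs.effects
    fixed = eff.subscription_cost + (
        annual_rtm_cost(inputs.rtm) if eff.bill_rtm_for_all_enrolled else 0.0
    )
    if include_reconciliation:
        fixed += inputs.settings.reconciliation_line
    other_savings = base.ed_visits * eff.ed_reduction + base.saba * eff.saba_reduction
    r_star = (fixed - other_savings) / base.hospitalizations
    f = lambda r: _difference_at_hosp_reduction(inputs, r, include_reconciliation)
    bisected = float(brentq(f, r_star - 1.0, r_star + 1.0, xtol=1e-12))
    return BreakEvenResult(
        value=r_star,
        residual=f(r_star),
        out_of_range=not 0.0 <= r_star <= 1.0,
        bisection_value=bisected,
    )


def budget_neutral_pdc(
    inputs: PayerInputs,
    *,
    hosp_link: float = 0.052,
    ed_link: float = 0.0115,
    per_pdc: float = 0.10,
    include_controller_costs: bool = False,
) -> BreakEvenResult:
    """PDC increase (percentage points) at which the budget impact is zero.

    The persistence linkage (``hosp_link``/``ed_link`` reductions per
    ``per_pdc`` of PDC) is treated as exactly linear. With controller costs
    included the added medication spend may dominate the linked savings, in
    which case no neutral point exists and an error is raised.
    """
    if hosp_link <= 0 or ed_link <= 0:
        raise ValueError("linkage reductions must be positive")
    base = baseline_breakdown(inputs)
    eff = inputs.effects
    fixed = eff.subscription_cost + (
        annual_rtm_cost(inputs.rtm) if eff.bill_rtm_for_all_enrolled else 0.0
    )
    fixed -= base.saba * eff.saba_reduction
    marginal = (
        base.hospitalizations * hosp_link / per_pdc
        + base.ed_visits * ed_link / per_pdc
    )
    if include_controller_costs:
        # marginal controller cost of one unit of PDC (linear, unclipped)
        daily = gold_weighted_mean(
            [controller_daily_cost(inputs.controller, g) for g in GOLD_GROUPS],
            inputs.gold_distribution,
        )
        marginal -= daily * inputs.settings.days_per_year
    if marginal <= 0:
        raise ValueError("no budget-neutral PDC increase exists under this linkage")
    delta = fixed / marginal

    def f(d: float) -> float:
        # remaining per-patient cost difference at a PDC increase of d
        return fixed - marginal * d

    residual = f(delta)
    bisected = float(brentq(f, delta - 1.0, delta + 1.0, xtol=1e-12))
    return BreakEvenResult(
        value=100.0 * delta,
        residual=residual,
        out_of_range=not 0.0 <= delta <= 1.0,
        bisection_value=100.0 * bisected,
    )
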