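"""Per-patient cost engine: GOLD weighting, category costs, arm breakdowns.

Hand-computed oracle values are derived in-line from the published inputs
by explicit per-group loops, independent of the engine's code path.
"""

import math

import pytest

from copd_bia.cost_engine import (
    CATEGORIES,
    CostBreakdown,
    annual_controller_cost,
    annual_medical_costs,
    annual_rtm_cost,
    annual_saba_cost,
    arm_breakdowns,
    baseline_breakdown,
    controller_daily_cost,
    enrolled_breakdown,
    gold_weighted_mean,
    group_breakdowns,
)
from copd_bia.parameters import GOLD_GROUPS, GoldDistribution
from copd_bia.reporting import render_currency
from copd_bia.synthetic_cohort import random_inputs

DIST = GoldDistribution(A=0.534, B=0.267, C=0.082, D=0.117)


def test_gold_weighted_mean_published_rates():
    # oracle: explicit sum over groups
    assert gold_weighted_mean((0.36, 0.46, 0.56, 0.56), DIST) == pytest.approx(
        0.534 * 0.36 + 0.267 * 0.46 + 0.082 * 0.56 + 0.117 * 0.56, rel=1e-12
    )
    assert gold_weighted_mean((0.36, 0.46, 0.56, 0.56), DIST) == pytest.approx(0.4265)
    assert gold_weighted_mean((0.11, 0.19, 0.22, 0.22), DIST) == pytest.approx(0.15325)
    assert gold_weighted_mean((7.0, 7.0, 7.0, 7.0), DIST) == pytest.approx(7.0)


def test_medical_costs_commercial(commercial_derived):
    x = commercial_derived
    med = annual_medical_costs(x.hcru, x.unit_costs, x.gold_distribution)
    assert med["outpatient_office"] == pytest.approx(2.64 * 126, rel=1e-12)
    assert med["ed_visits"] == pytest.approx(0.15325 * 3065, rel=1e-9)
    assert med["hospitalizations"] == pytest.approx(0.4265 * 25839, rel=1e-9)


def test_readmission_policies(commercial_derived):
    x = commercial_derived
    subset = annual_medical_costs(x.hcru, x.unit_costs, x.gold_distribution, "subset")
    separate = annual_medical_costs(
        x.hcru, x.unit_costs, x.gold_distribution, "separately_costed"
    )
    readmit_rate = gold_weighted_mean(x.hcru.readmissions, x.gold_distribution)
    assert separate["hospitalizations"] - subset["hospitalizations"] == pytest.approx(
        readmit_rate * x.unit_costs.hospitalization, rel=1e-9
    )
    with pytest.raises(ValueError, match="policy"):
        annual_medical_costs(x.hcru, x.unit_costs, x.gold_distribution, "bogus")


def test_medical_costs_zero_unit_costs(commercial_derived):
    x = commercial_derived
    zero = x.unit_costs.model_copy(
        update={"office_outpatient_visit": 0.0, "ed_visit": 0.0, "hospitalization": 0.0}
    )
    med = annual_medical_costs(x.hcru, zero, x.gold_distribution)
    assert all(v == 0.0 for v in med.values())


def test_saba_cost(commercial_derived, commercial_replication):
    # replication: published annual value passed through
    assert annual_saba_cost(
        commercial_replication.saba,
        commercial_replication.gold_distribution,
        commercial_replication.settings,
    ) == pytest.approx(292.0)
    # derived: weighted weekly puffs x weeks/year x mean WAC per actuation
    x = commercial_derived
    weekly = gold_weighted_mean(x.saba.weekly_puffs, x.gold_distribution)
    assert weekly == pytest.approx(7.42916, abs=1e-5)
    mean_wac = sum(p.price for p in x.saba.wac_prices) / len(x.saba.wac_prices)
    expected = weekly * (365.25 / 7) * mean_wac / x.saba.actuations_per_canister
    assert annual_saba_cost(x.saba, x.gold_distribution, x.settings) == pytest.approx(
        expected, rel=1e-12
    )


def test_saba_zero_puffs_and_empty_prices(commercial_derived):
    x = commercial_derived
    silent = x.saba.model_copy(
        update={"weekly_puffs": x.saba.weekly_puffs.model_copy(
            update={"A": 0.0, "B": 0.0, "C": 0.0, "D": 0.0})}
    )
    assert annual_saba_cost(silent, x.gold_distribution, x.settings) == 0.0
    no_prices = x.saba.model_copy(update={"wac_prices": []})
    with pytest.raises(ValueError, match="WAC"):
        annual_saba_cost(no_prices, x.gold_distribution, x.settings)


def test_controller_cost(commercial_derived):
    x = commercial_derived
    # oracle: explicit per-group mix average, PDC weighting and year length
    assert controller_daily_cost(x.controller, "A") == pytest.approx(
        0.4 * 14.80 + 0.2 * 10.40 + 0.4 * 17.14, rel=1e-12
    )
    expected = 0.0
    for g, share in x.gold_distribution.as_dict().items():
        daily = sum(
            x.controller.mix.for_group(g).as_dict()[c] * x.controller.daily_costs.as_dict()[c]
            for c in x.controller.daily_costs.as_dict()
        )
        expected += share * daily * getattr(x.controller.pdc, g) * 365.25
    got = annual_controller_cost(x.controller, x.gold_distribution, x.settings)
    assert got == pytest.approx(expected, rel=1e-12)
    assert render_currency(got) == "3,042"


def test_controller_cost_zero_pdc(commercial_derived):
    x = commercial_derived
    zero = x.controller.model_copy(
        update={"pdc": x.controller.pdc.model_copy(
            update={"A": 0.0, "B": 0.0, "C": 0.0, "D": 0.0})}
    )
    assert annual_controller_cost(zero, x.gold_distribution, x.settings) == 0.0


def test_controller_pdc_delta_clipped(commercial_derived):
    x = commercial_derived
    # shifting PDC far beyond 1 saturates every group at 1
    capped = annual_controller_cost(x.controller, x.gold_distribution, x.settings, 5.0)
    expected = sum(
        share * controller_daily_cost(x.controller, g) * 365.25
        for g, share in x.gold_distribution.as_dict().items()
    )
    assert capped == pytest.approx(expected, rel=1e-12)


def test_rtm_cost(commercial_derived):
    assert annual_rtm_cost(commercial_derived.rtm) == pytest.approx(
        1 * 19.38 + 6 * 55.72 + 6 * 50.18, rel=1e-12
    )
    assert render_currency(annual_rtm_cost(commercial_derived.rtm)) == "655"
    assert annual_rtm_cost([]) == 0.0
    entry = commercial_derived.rtm[0].model_copy(
        update={"annual_frequency": 12, "fee": 10.0}
    )
    assert annual_rtm_cost([entry]) == pytest.approx(120.0)


def test_replication_baselines(commercial_replication, medicare_replication):
    u = baseline_breakdown(commercial_replication)
    assert u.hospitalizations == 9918.0
    assert u.ed_visits == 462.0
    assert u.saba == 292.0
    assert u.propeller == u.rtm == u.reconciliation == 0.0
    assert render_currency(u.total) == "14,047"  # published total 14,048; ±1 rounding
    assert render_currency(baseline_breakdown(medicare_replication).total) == "8,990"


def test_enrolled_breakdown_effect_application(commercial_replication):
    x = commercial_replication
    u, e = arm_breakdowns(x)
    assert e.hospitalizations == pytest.approx(9918 * 0.7, rel=1e-12)
    assert e.ed_visits == pytest.approx(462 * 0.45, rel=1e-12)
    assert e.saba == pytest.approx(292 * (1 - 0.594), rel=1e-12)
    assert e.outpatient_office == u.outpatient_office
    assert e.controller == u.controller
    assert e.propeller == 200.0
    assert e.reconciliation == 73.0
    assert e.total == pytest.approx(sum(e.as_dict().values()), abs=1e-6)


def test_zero_effect_identity(commercial_replication):
    """With all reductions, fees and reconciliation at zero, enrollment
    changes nothing."""
    x = commercial_replication
    u = baseline_breakdown(x)
    eff = x.effects.model_copy(
        update={
            "hosp_reduction": 0.0,
            "ed_reduction": 0.0,
            "saba_reduction": 0.0,
            "subscription_cost": 0.0,
        }
    )
    e = enrolled_breakdown(
        u, eff, [], x.settings.model_copy(update={"reconciliation_line": 0.0})
    )
    assert all(
        getattr(e, c) == pytest.approx(getattr(u, c), abs=1e-12) for c in CATEGORIES
    )


def test_enrolled_costs_monotone_in_reductions(commercial_replication):
    x = commercial_replication
    u = baseline_breakdown(x)
    prev = math.inf
    for r in (0.0, 0.25, 0.5, 0.75, 1.0):
        eff = x.effects.model_copy(update={"hosp_reduction": r})
        e = enrolled_breakdown(u, eff, x.rtm, x.settings)
        assert e.hospitalizations <= prev
        prev = e.hospitalizations


@pytest.mark.parametrize("seed", [11, 12, 13])
def test_cost_linearity_in_unit_costs(seed):
    """Every category is homogeneous of degree one in its prices."""
    x = random_inputs(seed)
    k = 3.0
    scaled = x.model_copy(
        update={
            "unit_costs": x.unit_costs.model_copy(
                update={f: getattr(x.unit_costs, f) * k
                        for f in ("office_outpatient_visit", "ed_visit", "hospitalization")}
            ),
            "saba": x.saba.model_copy(
                update={"wac_prices": [p.model_copy(update={"price": p.price * k})
                                       for p in x.saba.wac_prices]}
            ),
            "controller": x.controller.model_copy(
                update={"daily_costs": x.controller.daily_costs.model_copy(
                    update={c: v * k for c, v in x.controller.daily_costs.as_dict().items()}
                )}
            ),
            "effects": x.effects.model_copy(
                update={"subscription_cost": x.effects.subscription_cost * k}
            ),
            "rtm": [e.model_copy(update={"fee": e.fee * k}) for e in x.rtm],
            "settings": x.settings.model_copy(
                update={"reconciliation_line": x.settings.reconciliation_line * k}
            ),
        }
    )
    for arm_idx in (0, 1):
        base = arm_breakdowns(x)[arm_idx]
        big = arm_breakdowns(scaled)[arm_idx]
        for c in CATEGORIES:
            assert getattr(big, c) == pytest.approx(k * getattr(base, c), rel=1e-9)


@pytest.mark.parametrize(
    "config", ["commercial_derived", "commercial_replication", "medicare_replication"]
)
def test_aggregate_equals_partition_weighted_groups(config, request):
    """Cost-then-aggregate equals aggregate-then-cost: the GOLD-weighted
    breakdown is the share-weighted average of per-group breakdowns."""
    x = request.getfixturevalue(config)
    agg_u, agg_e = arm_breakdowns(x)
    groups = group_breakdowns(x)
    shares = x.gold_distribution.as_dict()
    for idx, agg in ((0, agg_u), (1, agg_e)):
        for c in CATEGORIES:
            mixed = sum(shares[g] * getattr(groups[g][idx], c) for g in GOLD_GROUPS)
            assert mixed == pytest.approx(getattr(agg, c), rel=1e-9, abs=1e-9)
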