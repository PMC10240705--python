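"""Plan-level aggregation: per-member-per-month (PMPM) series and
aggregate expenditures.

PMPM is the payer budgeting unit: an annual plan-level amount divided by
(plan members x 12). The "without" view applies the unenrolled per-patient
cost to the whole eligible pool in every year; the "with" view mixes the
enrolled and unenrolled per-patient costs according to the uptake schedule;
"impact" is their difference, which collapses to the per-patient cost
difference applied to the enrolled count. The across-year average is the
unweighted arithmetic mean of the (unrounded) yearly values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from copd_bia.cost_engine import CATEGORIES, CostBreakdown
from copd_bia.population import PopulationCounts

VIEWS = ("without", "with", "impact")


@dataclass(frozen=True)
class PmpmSeries:
    """Per-category PMPM by year plus the across-year average, one view."""

    view: str
    frame: pd.DataFrame  # index: CATEGORIES + "total"; columns: years + "average"

    @property
    def years(self) -> list[int]:
        return [c for c in self.frame.columns if c != "average"]

    def category(self, name: str):
        return self.frame.loc[name]

    def average(self, name: str) -> float:
        return float(self.frame.loc[name, "average"])


@dataclass(frozen=True)
class ExpenditureReport:
    """Plan-level dollar totals for enrolled patients, by year and category."""

    frame: pd.DataFrame  # index: CATEGORIES + "total"; columns: years
    horizon_net_savings: float


def pmpm(annual_amount: float, members: float) -> float:
    """Convert an annual plan-level amount to per-member-per-month."""
    if members <= 0:
        raise ValueError("member count must be positive")
    return annual_amount / (members * 12.0)


def _series_frame(per_year: dict[str, np.ndarray], horizon: int) -> pd.DataFrame:
    years = list(range(1, horizon + 1))
    frame = pd.DataFrame(per_year, index=years).T
    frame.loc["total"] = frame.sum(axis=0)
    frame["average"] = frame[years].mean(axis=1)
    return frame


def pmpm_table(
    unenrolled: CostBreakdown,
    enrolled: CostBreakdown,
    counts: PopulationCounts,
    plan_size: float,
) -> dict[str, PmpmSeries]:
    """Build the three PMPM views (keys "without", "with", "impact")."""
    horizon = counts.horizon
    without = {}
    with_ = {}
    impact = {}
    for c in CATEGORIES:
        u = getattr(unenrolled, c)
        e = getattr(enrolled, c)
        without[c] = np.array(
            [pmpm(u * counts.eligible, plan_size) for _ in range(horizon)]
        )
        with_[c] = np.array(
            [
                pmpm(e * counts.enrolled[y] + u * counts.unenrolled[y], plan_size)
                for y in range(horizon)
            ]
        )
        impact[c] = with_[c] - without[c]
    return {
        "without": PmpmSeries("without", _series_frame(without, horizon)),
        "with": PmpmSeries("with", _series_frame(with_, horizon)),
        "impact": PmpmSeries("impact", _series_frame(impact, horizon)),
    }


def aggregate_expenditures(
    unenrolled: CostBreakdown,
    enrolled: CostBreakdown,
    counts: PopulationCounts,
) -> ExpenditureReport:
    """Plan-level expenditures on enrolled patients and horizon net savings.

    Expenditure per year and category = per-patient value x enrolled count.
    Horizon net savings = sum over years of (unenrolled total - enrolled
    total) x enrolled count.
    """
    per_year = {
        c: getattr(enrolled, c) * counts.enrolled for c in CATEGORIES
    }
    frame = _series_frame(per_year, counts.horizon).drop(columns="average")
    savings = float(
        np.sum((unenrolled.total - enrolled.total) * counts.enrolled)
    )
    return ExpenditureReport(frame=frame, horizon_net_savings=savings)
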