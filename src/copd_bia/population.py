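"""Eligible population and uptake arithmetic.

Eligibility: plan members aged >= 40 with COPD. The <40 age band is
structurally excluded; the eligible pool is constant over the horizon (no
incidence, mortality or disenrollment), and the uptake fraction enrolls
patients for the entirety of each year. Counts are kept as reals
internally; rounding to whole patients happens only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from copd_bia.parameters import (
    GOLD_GROUPS,
    GoldDistribution,
    PayerInputs,
    PayerPopulation,
    PrevalenceByAge,
)


@dataclass(frozen=True)
class PopulationCounts:
    """Eligible pool and its yearly enrolled/unenrolled split."""

    eligible: float
    enrolled: np.ndarray  # one entry per horizon year
    unenrolled: np.ndarray
    gold_counts: dict = field(default_factory=dict)

    @property
    def horizon(self) -> int:
        return len(self.enrolled)


def eligible_patients(pop: PayerPopulation, prev: PrevalenceByAge) -> float:
    """Eligible COPD patients: plan size x sum over >=40 bands of
    (age share x band prevalence)."""
    return pop.plan_size * (
        pop.age_shares.age_40_64 * prev.age_40_64
        + pop.age_shares.age_65_plus * prev.age_65_plus
    )


def enrolled_counts(
    eligible: float, uptake: list[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-year (enrolled, unenrolled) counts under the uptake schedule."""
    if eligible < 0:
        raise ValueError("eligible count must be >= 0")
    up = np.asarray(uptake, dtype=float)
    enrolled = eligible * up
    return enrolled, eligible - enrolled


def gold_partition(count: float, dist: GoldDistribution) -> dict[str, float]:
    """Split a patient count across GOLD ABCD groups (unrounded reals)."""
    if count < 0:
        raise ValueError("count must be >= 0")
    return {g: count * share for g, share in dist.as_dict().items()}


def population_counts(inputs: PayerInputs) -> PopulationCounts:
    eligible = eligible_patients(inputs.population, inputs.prevalence)
    enrolled, unenrolled = enrolled_counts(eligible, inputs.uptake)
    return PopulationCounts(
        eligible=eligible,
        enrolled=enrolled,
        unenrolled=unenrolled,
        gold_counts=gold_partition(eligible, inputs.gold_distribution),
    )


def population_table(inputs: PayerInputs) -> pd.DataFrame:
    """Year-by-year population table (one row per horizon year)."""
    counts = population_counts(inputs)
    rows = []
    for y in range(counts.horizon):
        row = {
            "year": y + 1,
            "eligible": counts.eligible,
            "enrolled": counts.enrolled[y],
            "unenrolled": counts.unenrolled[y],
        }
        for g in GOLD_GROUPS:
            row[f"gold_{g}"] = counts.gold_counts[g]
        rows.append(row)
    return pd.DataFrame(rows)
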