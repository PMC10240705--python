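"""Reporting layer: currency rendering, table writers, run manifests.

Rounding discipline: internal arithmetic is unrounded throughout the
package; dollars are rounded half-up exactly once, at render time (whole
dollars with thousands separators, PMPM at 2 decimals, aggregate
expenditures at 1 decimal of millions). Summing rendered categories may
therefore differ from a rendered total by about $1 per handful of
categories; unrounded sums match exactly and are preserved in the JSON
mirrors.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from copd_bia.budget_impact import aggregate_expenditures, pmpm_table
from copd_bia.cost_engine import CATEGORIES, arm_breakdowns, CostBreakdown
from copd_bia.parameters import PayerInputs
from copd_bia.population import population_counts, population_table

RENDER_LAYERS = ("dollars", "pmpm", "millions")


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of the printed tables,
    not banker's rounding)."""
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"cannot round non-finite value {value}")
    q = Decimal(1).scaleb(-decimals)
    # "+ 0.0" folds IEEE negative zero into plain zero
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP)) + 0.0


def render_currency(value: float, layer: str = "dollars") -> str:
    """Format a currency amount for one reporting layer.

    ``dollars``: half-up integer with thousands separators; ``pmpm``: two
    decimals; ``millions``: one decimal of millions.
    """
    if layer not in RENDER_LAYERS:
        raise ValueError(f"unknown layer {layer!r}; choose from {RENDER_LAYERS}")
    if not math.isfinite(value):
        raise ValueError(f"cannot render non-finite value {value}")
    if layer == "dollars":
        return f"{int(round_half_up(value, 0)):,}"
    if layer == "pmpm":
        return f"{round_half_up(value, 2):.2f}"
    return f"{round_half_up(value / 1e6, 1):.1f}"


@dataclass
class RunManifest:
    """Provenance for one output set; re-running from it reproduces the
    CSV outputs byte for byte."""

    config: str
    subcommand: str
    options: dict = field(default_factory=dict)
    output_dir: str = ""
    timestamp: str = ""
    package_version: str = ""
    seed: int | None = None

    def write(self, out_dir: Path) -> Path:
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path


def _new_manifest(config: str, subcommand: str, out_dir: Path, **options) -> RunManifest:
    from copd_bia import __version__

    seed = options.pop("seed", None)
    return RunManifest(
        config=str(config),
        subcommand=subcommand,
        options=options,
        output_dir=str(out_dir),
        timestamp=datetime.now(timezone.utc).isoformat(),
        package_version=__version__,
        seed=seed,
    )


def breakdown_frame(unenrolled: CostBreakdown, enrolled: CostBreakdown) -> pd.DataFrame:
    """Per-patient annual cost table: categories x (unenrolled, enrolled,
    difference), unrounded."""
    rows = {}
    for c in CATEGORIES:
        u, e = getattr(unenrolled, c), getattr(enrolled, c)
        rows[c] = {"unenrolled": u, "enrolled": e, "difference": e - u}
    rows["total"] = {
        "unenrolled": unenrolled.total,
        "enrolled": enrolled.total,
        "difference": enrolled.total - unenrolled.total,
    }
    return pd.DataFrame(rows).T


def rendered_breakdown_frame(
    unenrolled: CostBreakdown, enrolled: CostBreakdown
) -> pd.DataFrame:
    frame = breakdown_frame(unenrolled, enrolled)
    return frame.map(lambda v: render_currency(v, "dollars"))


def run_full_analysis(
    inputs: PayerInputs, out_dir: str | Path, config_label: str = "<inline>"
) -> dict:
    """Execute the base-case pipeline and write the report bundle.

    Writes the population table, per-patient breakdown, the three PMPM
    views, the expenditure report, an unrounded JSON summary and a run
    manifest. Returns the in-memory bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = population_counts(inputs)
    unenrolled, enrolled = arm_breakdowns(inputs)
    views = pmpm_table(unenrolled, enrolled, counts, inputs.plan_size)
    expend = aggregate_expenditures(unenrolled, enrolled, counts)

    population_table(inputs).to_csv(out / "population.csv", index=False)
    breakdown_frame(unenrolled, enrolled).to_csv(out / "per_patient_costs.csv")
    for name, series in views.items():
        series.frame.to_csv(out / f"pmpm_{name}.csv")
    expend.frame.to_csv(out / "expenditures.csv")

    summary = {
        "payer": inputs.payer,
        "eligible_patients": counts.eligible,
        "enrolled_by_year": [float(x) for x in counts.enrolled],
        "per_patient_unenrolled_total": unenrolled.total,
        "per_patient_enrolled_total": enrolled.total,
        "per_patient_difference": enrolled.total - unenrolled.total,
        "pmpm_impact_average": views["impact"].average("total"),
        "horizon_net_savings": expend.horizon_net_savings,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest = _new_manifest(config_label, "run", out)
    manifest.write(out)
    return {
        "counts": counts,
        "unenrolled": unenrolled,
        "enrolled": enrolled,
        "pmpm": views,
        "expenditures": expend,
        "summary": summary,
        "manifest": manifest,
    }
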