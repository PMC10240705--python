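"""One-way sensitivity sweeps, break-even hospitalization reduction and
budget-neutral persistence increase for both payers.

Finds: varying medical unit costs or the HCRU effect sizes by ±10%/±25%
moves the commercial per-enrollee saving between about $1,668 and $3,283;
the program breaks even at a 4.31% (commercial) / 11.15% (Medicare)
hospitalization reduction, and — under the persistence linkage with
controller costs excluded — at PDC increases of 13.08 / 24.78 percentage
points.
"""

from pathlib import Path

import pandas as pd

from copd_bia import load_builtin
from copd_bia.reporting import round_half_up
from copd_bia.scenarios import (
    SENSITIVITY_PARAMETERS,
    break_even_hosp_reduction,
    budget_neutral_pdc,
    one_way_sensitivity,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "sensitivity"
CHANGES = [-0.25, -0.10, 0.10, 0.25]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for payer in ("commercial", "medicare"):
        inputs = load_builtin(f"{payer}_replication")
        rows = {}
        for param in SENSITIVITY_PARAMETERS:
            result = one_way_sensitivity(inputs, param, CHANGES)
            rows[param] = {
                f"{c:+.0%}": round_half_up(v, 2)
                for c, v in zip(result.relative_changes, result.savings)
            }
            rows[param]["base"] = round_half_up(result.base_saving, 2)
        table = pd.DataFrame(rows).T
        table.to_csv(OUT / f"{payer}_sensitivity.csv")
        print(f"{payer} per-enrollee annual saving (USD):")
        print(table.to_string())
        be = break_even_hosp_reduction(inputs)
        bn = budget_neutral_pdc(inputs)
        print(
            f"{payer}: break-even hospitalization reduction {be.value:.5%} "
            f"(residual {be.residual:.1e}); budget-neutral PDC increase "
            f"{bn.value:.2f} points"
        )
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
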