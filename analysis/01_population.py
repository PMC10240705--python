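"""Eligible COPD populations and uptake projections for both payers.

Finds: 5M-member commercial and Medicare plans contain 212,200 and 606,600
eligible COPD patients (aged >= 40); the 10/15/30% uptake schedule enrolls
21,220/31,830/63,660 (commercial) and 60,660/90,990/181,980 (Medicare)
patients in years 1-3.
"""

from pathlib import Path

from copd_bia import load_builtin
from copd_bia.population import population_table
from copd_bia.reporting import render_currency

OUT = Path(__file__).resolve().parents[1] / "results" / "population"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for payer in ("commercial", "medicare"):
        inputs = load_builtin(f"{payer}_derived")
        table = population_table(inputs)
        table.to_csv(OUT / f"{payer}.csv", index=False)
        eligible = table["eligible"].iloc[0]
        enrolled = [render_currency(v) for v in table["enrolled"]]
        print(f"{payer}: eligible {render_currency(eligible)}; "
              f"enrolled by year {', '.join(enrolled)}")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
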