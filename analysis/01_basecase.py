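#!/usr/bin/env python
"""Base-case cost-effectiveness of antivenom in the 16 countries.

Evaluates the decision tree per country with the packaged inputs and writes
the base-case grid (ICER per DALY averted, cost per death averted, threshold
classification at one times GDP per capita, plus the five standard scenario
columns) to results/basecase.csv.
"""

from pathlib import Path

from snakebite_cea import build_results_table, load_assumptions, load_country_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    countries = load_country_table()
    ga, ci = load_assumptions()
    grid = build_results_table(countries, ga, ci)

    OUT.mkdir(exist_ok=True)
    grid.round(2).to_csv(OUT / "basecase.csv")

    icers = grid["icer_per_daly"]
    cpd = grid["cost_per_death_averted"]
    print(f"Cost per death averted ranges from ${cpd.min():,.0f} ({cpd.idxmin()}) "
          f"to ${cpd.max():,.0f} ({cpd.idxmax()}).")
    print(f"Cost per DALY averted ranges from ${icers.min():,.0f} ({icers.idxmin()}) "
          f"to ${icers.max():,.0f} ({icers.idxmax()}).")
    below = int(grid["cost_effective"].sum())
    print(f"{below}/16 countries fall below their 1x GDP-per-capita threshold "
          "in the base case.")
    print(f"Wrote {OUT / 'basecase.csv'}")


if __name__ == "__main__":
    main()
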