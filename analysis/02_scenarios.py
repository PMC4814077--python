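#!/usr/bin/env python
"""Scenario analyses: price changes, snake mix, nil non-CV effectiveness,
paid comparator care, adrenaline premedication, alternative disabilities.

Writes one row per country x scenario to results/scenarios.csv and reports
which cells cross the cost-effectiveness threshold.
"""

from pathlib import Path

import pandas as pd

from snakebite_cea import load_assumptions, load_country_table, run_country
from snakebite_cea.sensitivity import BUILTIN_SCENARIOS

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    countries = load_country_table()
    ga, ci = load_assumptions()

    rows = []
    for cp in countries:
        for name in BUILTIN_SCENARIOS:
            res = run_country(cp, ga, ci, scenario=name)
            rows.append(
                {
                    "country": cp.country_id,
                    "scenario": name,
                    "icer_per_daly": res.icer_per_daly,
                    "cost_per_death_averted": res.cost_per_death_averted,
                    "cost_effective": res.cost_effective,
                }
            )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.round(2).to_csv(OUT / "scenarios.csv", index=False)

    crossed = df[~df.cost_effective]
    print("Cells above the 1x GDP threshold:")
    for _, row in crossed.iterrows():
        print(f"  {row.country} / {row.scenario}: ${row.icer_per_daly:,.2f} per DALY")
    base = {cp.country_id: run_country(cp, ga, ci).icer_per_daly for cp in countries}
    adren = df[df.scenario == "adrenaline_premed"].set_index("country").icer_per_daly
    assert all(adren[c] <= base[c] for c in base)
    print("Adrenaline premedication lowers every country's ICER slightly "
          f"(e.g. benin {base['benin']:.2f} -> {adren['benin']:.2f}).")
    print(f"Wrote {OUT / 'scenarios.csv'}")


if __name__ == "__main__":
    main()
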