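# snakebite-cea

Decision-analytic cost-effectiveness model of snakebite antivenom for 16
West African countries, built as a tested, reusable pipeline: decision-tree
evaluation, discounted DALY accounting, incremental cost-effectiveness
ratios (ICERs), scenario and one-way (tornado) sensitivity analysis, and
probabilistic sensitivity analysis (PSA) against per-capita-GDP
willingness-to-pay thresholds.

Snakebite envenoming — dominated in the West African savannah by the carpet
viper (*Echis* spp.) — kills thousands per year, and effective antivenoms
are scarce and unevenly priced. For each country the model compares two
arms for an envenomed patient: access to an effective antivenom (triaged by
the 20-minute whole blood clotting test into monospecific or polyspecific
product, with early-adverse-reaction risk) versus no antivenom. Outputs per
patient are expected cost, death probability, amputation probability and
expected DALYs; the decision statistics are

* ΔC / Δdeaths — incremental cost per death averted, and
* ΔC / ΔDALYs — incremental cost per DALY averted (the ICER), where a DALY
  combines years of life lost, `YLL = (1 − (1+r)^(−L))/r` at r = 3%, with
  years lived with disability, `YLD = dw · YLL` (amputation weight
  dw = 0.102),

classified cost-effective when the ICER falls strictly below one times the
country's GDP per capita.

The package is aimed at health-economics and neglected-tropical-disease
researchers who want the full model as inspectable, scriptable code rather
than a spreadsheet or proprietary tree: every input is a packaged CSV/YAML
value, every convention is an isolated function, and a patient-level
microsimulation oracle cross-checks the closed-form evaluation.

## Worked example

```python
from snakebite_cea import load_country_table, load_assumptions, run_country, run_psa

countries = {c.country_id: c for c in load_country_table()}
ga, ci = load_assumptions()

base = run_country(countries["benin"], ga, ci)
print(f"ICER  ${base.icer_per_daly:.2f}/DALY averted")
print(f"Cost  ${base.cost_per_death_averted:.2f}/death averted")
print(f"below 1x GDP ($751): {base.cost_effective}")

double_dose = run_country(countries["benin"], ga, ci, scenario="av_cost_306")
print(f"ICER at $306 antivenom: ${double_dose.icer_per_daly:.2f}")

psa = run_psa(countries["benin"], ga, ci, n=10_000, seed=20160330)
print(f"PSA 95% interval (${psa.percentile_2_5:.0f}, ${psa.percentile_97_5:.0f}), "
      f"P(cost-effective) = {psa.prob_cost_effective:.2%}")
```

prints

```
ICER  $82.76/DALY averted
Cost  $2001.19/death averted
below 1x GDP ($751): True
ICER at $306 antivenom: $136.09
PSA 95% interval ($54, $137), P(cost-effective) = 100.00%
```

i.e. averting one death by treating envenomed patients in Benin costs about
$2,000; per discounted DALY the price is ~$83, an order of magnitude below
Benin's GDP per capita, and the conclusion survives doubling the antivenom
price and joint sampling of all uncertain inputs. Across the 16 countries
the base-case ICER runs from ~$83 (Benin) to ~$284 (Sierra Leone) per DALY
averted — below every country's threshold.

## Analysis scripts

The numbered drivers under `analysis/` rebuild each stage and write tables
under `results/`:

| script | writes |
|---|---|
| `01_basecase.py` | per-country base-case grid with scenario columns |
| `02_scenarios.py` | all named scenarios, threshold crossings |
| `03_tornado.py` | ranked one-way sensitivity entries per country |
| `04_psa.py` | PSA intervals, probabilities, acceptability curves |
| `05_oracle_check.py` | microsimulation vs closed form (z-scores) |

The same functionality is exposed on the command line via the `cea` entry
point (`cea basecase`, `cea scenario --name ncv_eff_zero`, `cea tornado
--country guinea_bissau`, `cea psa`, `cea oracle --country benin`).

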