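"""Per-country base-case analysis and the full country x scenario results grid.

The headline statistic is the incremental cost-effectiveness ratio (ICER):
incremental cost divided by incremental effect, reported both per DALY
averted and per death averted, and classified against a willingness-to-pay
threshold of one times the country's GDP per capita ("cost-effective" means
strictly below the threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import sensitivity as _sensitivity
from .daly import daly_constants
from .parameters import CostInputs, CountryParameters, GlobalAssumptions
from .tree import ArmOutcome, Incremental, arm_expectation, incremental

__all__ = [
    "DominanceError",
    "ICERResult",
    "icer_per_daly",
    "cost_per_death_averted",
    "classify_cost_effectiveness",
    "run_country",
    "build_results_table",
    "REPORT_SCENARIOS",
]

#: Scenario columns of the published results grid, in print order.
REPORT_SCENARIOS = (
    "av_cost_125",
    "av_cost_306",
    "pcv_zero",
    "ncv_eff_zero",
    "comparator_65_63",
)


class DominanceError(ValueError):
    """The incremental effect is not positive, so a conventional ICER is undefined."""


@dataclass(frozen=True)
class ICERResult:
    country_id: str
    scenario_label: str
    icer_per_daly: float
    cost_per_death_averted: float
    cost_effective: bool
    treated: ArmOutcome
    untreated: ArmOutcome
    incremental: Incremental


def icer_per_daly(inc: Incremental) -> float:
    """Incremental cost per DALY averted (USD/DALY)."""
    if inc.dalys_averted <= 0:
        raise DominanceError(
            f"dalys_averted={inc.dalys_averted!r} is not positive; ICER undefined"
        )
    return inc.delta_cost / inc.dalys_averted


def cost_per_death_averted(inc: Incremental) -> float:
    """Incremental cost per death averted (USD/death)."""
    if inc.deaths_averted <= 0:
        raise DominanceError(
            f"deaths_averted={inc.deaths_averted!r} is not positive; ratio undefined"
        )
    return inc.delta_cost / inc.deaths_averted


def classify_cost_effectiveness(icer: float, gdp_per_capita: float) -> bool:
    """True iff the ICER falls strictly below one times GDP per capita."""
    if icer <= 0 or gdp_per_capita <= 0:
        raise ValueError("icer and gdp_per_capita must be positive")
    return icer < gdp_per_capita


def run_country(
    cp: CountryParameters,
    ga: GlobalAssumptions,
    ci: CostInputs,
    scenario: "_sensitivity.ScenarioSpec | str | None" = None,
) -> ICERResult:
    """Evaluate one country's decision tree and ICERs, optionally under a scenario."""
    label = "base_case"
    if scenario is not None:
        if isinstance(scenario, str):
            scenario = _sensitivity.get_scenario(scenario)
        cp, ga, ci = _sensitivity.apply_scenario(cp, ga, ci, scenario)
        label = scenario.label

    dc = daly_constants(cp, ga)
    treated = arm_expectation("treated", cp, ga, ci, dc)
    untreated = arm_expectation("untreated", cp, ga, ci, dc)
    inc = incremental(treated, untreated)
    icer = icer_per_daly(inc)
    return ICERResult(
        country_id=cp.country_id,
        scenario_label=label,
        icer_per_daly=icer,
        cost_per_death_averted=cost_per_death_averted(inc),
        cost_effective=classify_cost_effectiveness(icer, cp.gdp_per_capita),
        treated=treated,
        untreated=untreated,
        incremental=inc,
    )


def build_results_table(
    countries: list[CountryParameters],
    ga: GlobalAssumptions,
    ci: CostInputs,
    scenarios: tuple[str, ...] = REPORT_SCENARIOS,
) -> pd.DataFrame:
    """One row per country: base-case ICER, cost/death averted, scenario ICERs.

    Values are full precision; round only for presentation.
    """
    rows = []
    for cp in countries:
        base = run_country(cp, ga, ci)
        row = {
            "country": cp.country_id,
            "gdp_per_capita": cp.gdp_per_capita,
            "icer_per_daly": base.icer_per_daly,
            "cost_per_death_averted": base.cost_per_death_averted,
            "cost_effective": base.cost_effective,
        }
        for name in scenarios:
            row[f"icer_{name}"] = run_country(cp, ga, ci, scenario=name).icer_per_daly
        rows.append(row)
    return pd.DataFrame(rows).set_index("country")
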