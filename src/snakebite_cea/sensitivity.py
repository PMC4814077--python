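"""Scenario analysis and one-way (tornado) sensitivity.

A scenario is a pure, declarative bundle of overrides applied on top of the
base-case inputs: absolute field overrides on the country row, the global
assumptions or the cost bundle, a multiplicative modifier on both EAR risks
(adrenaline premedication), and an alternative-disability substitution
(blindness or PTSD replacing amputation, both probability and weight).

One-way sensitivity re-evaluates the country ICER at the low and high end of
one parameter's range with everything else held at base case; the tornado is
the list of such entries sorted by descending ICER spread.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .parameters import (
    CostInputs,
    CountryParameters,
    GlobalAssumptions,
    validate_parameters,
)

__all__ = [
    "ScenarioSpec",
    "TornadoEntry",
    "BUILTIN_SCENARIOS",
    "get_scenario",
    "apply_scenario",
    "one_way",
    "tornado",
    "DEFAULT_TORNADO_RANGES",
]


@dataclass(frozen=True)
class ScenarioSpec:
    label: str
    country_overrides: dict = field(default_factory=dict)
    global_overrides: dict = field(default_factory=dict)
    cost_overrides: dict = field(default_factory=dict)
    ear_multiplier: float = 1.0
    #: (probability, disability weight) replacing amputation, or None.
    disability: tuple[float, float] | None = None


BUILTIN_SCENARIOS: dict[str, ScenarioSpec] = {
    "av_cost_125": ScenarioSpec("av_cost_125", cost_overrides={"c_antivenom": 125.0}),
    "av_cost_306": ScenarioSpec("av_cost_306", cost_overrides={"c_antivenom": 306.0}),
    "pcv_zero": ScenarioSpec("pcv_zero", country_overrides={"p_cv": 0.0}),
    "ncv_eff_zero": ScenarioSpec("ncv_eff_zero", country_overrides={"av_eff_ncv": 0.0}),
    "comparator_65_63": ScenarioSpec(
        "comparator_65_63", cost_overrides={"c_no_antivenom": 65.63}
    ),
    "adrenaline_premed": ScenarioSpec("adrenaline_premed", ear_multiplier=1.0 - 0.40),
    "disability_blindness": ScenarioSpec(
        "disability_blindness", disability=(0.0001, 0.552)
    ),
    "disability_ptsd": ScenarioSpec("disability_ptsd", disability=(0.20, 0.105)),
}


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return BUILTIN_SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {sorted(BUILTIN_SCENARIOS)}"
        ) from None


def apply_scenario(
    cp: CountryParameters,
    ga: GlobalAssumptions,
    ci: CostInputs,
    spec: ScenarioSpec,
) -> tuple[CountryParameters, GlobalAssumptions, CostInputs]:
    """Return modified copies of the inputs; the originals are untouched."""
    cp = cp.replace(**spec.country_overrides) if spec.country_overrides else cp
    ga = ga.replace(**spec.global_overrides) if spec.global_overrides else ga
    ci = ci.replace(**spec.cost_overrides) if spec.cost_overrides else ci
    if spec.ear_multiplier != 1.0:
        cp = cp.replace(
            p_ear_mono=cp.p_ear_mono * spec.ear_multiplier,
            p_ear_poly=cp.p_ear_poly * spec.ear_multiplier,
        )
    if spec.disability is not None:
        p, dw = spec.disability
        ga = ga.replace(p_disabl=p, dw_amputation=dw)
    problems = validate_parameters(cp, ga, ci)
    if problems:
        raise ValueError(f"scenario {spec.label!r} violates invariants: {problems}")
    return cp, ga, ci


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


_COUNTRY_FIELDS = {f.name for f in dataclasses.fields(CountryParameters)}
_GLOBAL_FIELDS = {f.name for f in dataclasses.fields(GlobalAssumptions)}
_COST_FIELDS = {f.name for f in dataclasses.fields(CostInputs)}

#: Default one-way ranges. Probability/effectiveness ranges are the spans of
#: base-case values reported across countries (the same envelopes the PSA
#: uses); the antivenom cost range is the pair of published price scenarios;
#: the remaining cost items and the unranged probabilities use +/-20% and
#: plausible spans documented in the methods note.
DEFAULT_TORNADO_RANGES: dict[str, tuple[float, float]] = {
    "p_cv": (0.01, 0.85),
    "p_cv_mort_untreated": (0.081, 0.1583),
    "p_ncv_mort_untreated": (0.05, 0.273),
    "av_eff_cv": (0.5643, 0.92),
    "av_eff_ncv": (0.436, 0.92),
    "p_ear_mono": (0.033, 0.19),
    "p_ear_poly": (0.033, 0.26),
    "p_ear_mort": (0.0, 0.02),
    "p_disabl": (0.01, 0.06),
    "c_antivenom": (125.0, 306.0),
    "c_20wbct": (2.5, 3.75),
    "c_adv_reaction": (1.5, 2.25),
    "c_supp_care": (15.0, 22.5),
    "c_feed_transp": (35.0, 52.5),
    "c_refrg_transp": (15.0, 22.5),
}


def _override_spec(parameter: str, value: float) -> ScenarioSpec:
    if parameter in _COUNTRY_FIELDS:
        return ScenarioSpec(f"{parameter}={value}", country_overrides={parameter: value})
    if parameter in _GLOBAL_FIELDS:
        return ScenarioSpec(f"{parameter}={value}", global_overrides={parameter: value})
    if parameter in _COST_FIELDS:
        return ScenarioSpec(f"{parameter}={value}", cost_overrides={parameter: value})
    valid = sorted(_COUNTRY_FIELDS | _GLOBAL_FIELDS | _COST_FIELDS)
    raise KeyError(f"unknown parameter {parameter!r}; valid names: {valid}")


def one_way(
    cp: CountryParameters,
    ga: GlobalAssumptions,
    ci: CostInputs,
    parameter: str,
    low: float,
    high: float,
) -> TornadoEntry:
    """ICER at the low and high value of one parameter, all else at base case."""
    from .pipeline import run_country

    if low > high:
        raise ValueError(f"low={low!r} exceeds high={high!r}")
    icer_low = run_country(cp, ga, ci, scenario=_override_spec(parameter, low)).icer_per_daly
    icer_high = run_country(cp, ga, ci, scenario=_override_spec(parameter, high)).icer_per_daly
    return TornadoEntry(parameter, low, high, icer_low, icer_high)


def tornado(
    cp: CountryParameters,
    ga: GlobalAssumptions,
    ci: CostInputs,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> list[TornadoEntry]:
    """One-way entries for every ranged parameter, sorted by descending spread."""
    ranges = DEFAULT_TORNADO_RANGES if ranges is None else ranges
    entries = [
        one_way(cp, ga, ci, name, low, high) for name, (low, high) in ranges.items()
    ]
    return sorted(entries, key=lambda e: (-e.spread, e.parameter))
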