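"""Analytic evaluation of the two-arm decision tree for one envenomed patient.

Structure of the tree: an envenoming is caused by a carpet viper with
probability p_cv. In the treated arm the 20WBCT triages the patient: a
carpet-viper bite receives monospecific antivenom (EAR risk p_ear_mono), any
other bite receives polyspecific antivenom (EAR risk p_ear_poly). Antivenom
multiplies the untreated case fatality by (1 - effectiveness); an EAR adds
its own 1% mortality, compounded independently with the residual envenoming
mortality. Survivors of either arm suffer amputation with probability
p_disabl. The untreated arm has no triage, no EAR, and (in the base case) no
cost.

The branch arithmetic is written against plain floats/NumPy arrays so the
probabilistic sensitivity analysis can evaluate thousands of parameter draws
vectorised; `arm_expectation` wraps the scalar case into `ArmOutcome`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .daly import DalyConstants
from .parameters import CostInputs, CountryParameters, GlobalAssumptions

__all__ = [
    "ArmOutcome",
    "Incremental",
    "post_av_mortality",
    "effectiveness_from_counts",
    "branch_death_probability",
    "untreated_death_probability",
    "treated_death_probability",
    "mixture_ear_probability",
    "treated_expected_cost",
    "arm_expectation",
    "incremental",
]


def post_av_mortality(p_untreated, effectiveness):
    """Mortality after antivenom: untreated mortality x (1 - effectiveness)."""
    _check_unit("p_untreated", p_untreated)
    _check_unit("effectiveness", effectiveness)
    return p_untreated * (1.0 - effectiveness)


def effectiveness_from_counts(
    untreated_deaths: float,
    untreated_n: float,
    treated_deaths: float,
    treated_n: float,
) -> float:
    """Effectiveness (c - d)/c from death counts, i.e. 1 - relative risk.

    c and d are the untreated and treated case-fatality proportions. The raw
    value is returned (it can be negative if treatment looks harmful);
    clipping to [0, 1] is a reporting concern.
    """
    if min(untreated_deaths, untreated_n, treated_deaths, treated_n) < 0:
        raise ValueError("counts must be non-negative")
    if untreated_n <= 0 or treated_n <= 0:
        raise ValueError("denominators must be positive")
    if untreated_deaths > untreated_n or treated_deaths > treated_n:
        raise ValueError("deaths cannot exceed the group size")
    c = untreated_deaths / untreated_n
    if c == 0:
        raise ZeroDivisionError(
            "effectiveness undefined: no deaths among the untreated"
        )
    d = treated_deaths / treated_n
    return (c - d) / c


def branch_death_probability(p_mort_av, p_ear, p_ear_mort):
    """Death probability on a treated branch with EAR as an extra hazard.

    EAR mortality compounds independently with the residual envenoming
    mortality: an EAR patient dies of the reaction with probability
    p_ear_mort, and if not, still faces p_mort_av. This compounding
    convention is isolated here so it can be swapped.
    """
    _check_unit("p_mort_av", p_mort_av)
    _check_unit("p_ear", p_ear)
    _check_unit("p_ear_mort", p_ear_mort)
    with_ear = p_ear_mort + (1.0 - p_ear_mort) * p_mort_av
    return p_ear * with_ear + (1.0 - p_ear) * p_mort_av


def untreated_death_probability(p_cv, p_cv_mort, p_ncv_mort):
    """Mixture case fatality without antivenom."""
    return p_cv * p_cv_mort + (1.0 - p_cv) * p_ncv_mort


def treated_death_probability(
    p_cv, p_cv_mort, p_ncv_mort, av_eff_cv, av_eff_ncv, p_ear_mono, p_ear_poly, p_ear_mort
):
    """Mixture case fatality with antivenom, mono/poly EAR risk per branch."""
    cv = branch_death_probability(
        post_av_mortality(p_cv_mort, av_eff_cv), p_ear_mono, p_ear_mort
    )
    ncv = branch_death_probability(
        post_av_mortality(p_ncv_mort, av_eff_ncv), p_ear_poly, p_ear_mort
    )
    return p_cv * cv + (1.0 - p_cv) * ncv


def mixture_ear_probability(p_cv, p_ear_mono, p_ear_poly):
    """Overall EAR probability across the 20WBCT-triaged branches."""
    return p_cv * p_ear_mono + (1.0 - p_cv) * p_ear_poly


def treated_expected_cost(ci: CostInputs, p_ear_mix):
    """Per-patient treated-arm cost; EAR management weighted by EAR risk.

    The 20WBCT is charged to every treated patient (it is the triage step
    for both branches); EAR deaths incur the full bundle (treatment was
    given). Costs are never discounted.
    """
    return ci.fixed_treated_cost + p_ear_mix * ci.c_adv_reaction


@dataclass(frozen=True)
class ArmOutcome:
    """Expected per-patient outcomes for one arm of the tree."""

    arm_label: str
    expected_cost: float
    p_death: float
    p_amputation: float
    expected_dalys: float


@dataclass(frozen=True)
class Incremental:
    """Treated-minus-untreated differences (averted quantities are untreated minus treated)."""

    delta_cost: float
    deaths_averted: float
    amputations_averted: float
    dalys_averted: float


def arm_expectation(
    arm: str,
    cp: CountryParameters,
    ga: GlobalAssumptions,
    ci: CostInputs,
    dc: DalyConstants,
) -> ArmOutcome:
    """Expected cost, death/amputation probability and DALYs for one arm.

    ``arm`` is ``"treated"`` or ``"untreated"``. Amputation strikes all
    survivors at ``p_disabl`` in both arms (antivenom has no effect on
    amputation in the base case).
    """
    if arm == "untreated":
        p_death = untreated_death_probability(
            cp.p_cv, cp.p_cv_mort_untreated, cp.p_ncv_mort_untreated
        )
        cost = ci.c_no_antivenom
    elif arm == "treated":
        p_death = treated_death_probability(
            cp.p_cv,
            cp.p_cv_mort_untreated,
            cp.p_ncv_mort_untreated,
            cp.av_eff_cv,
            cp.av_eff_ncv,
            cp.p_ear_mono,
            cp.p_ear_poly,
            ga.p_ear_mort,
        )
        cost = treated_expected_cost(
            ci, mixture_ear_probability(cp.p_cv, cp.p_ear_mono, cp.p_ear_poly)
        )
    else:
        raise ValueError(f"arm must be 'treated' or 'untreated', got {arm!r}")

    p_amputation = (1.0 - p_death) * ga.p_disabl
    expected_dalys = p_death * dc.yll_per_death + p_amputation * dc.yld_per_disability
    return ArmOutcome(
        arm_label=arm,
        expected_cost=float(cost),
        p_death=float(p_death),
        p_amputation=float(p_amputation),
        expected_dalys=float(expected_dalys),
    )


def incremental(treated: ArmOutcome, untreated: ArmOutcome) -> Incremental:
    """Componentwise incremental quantities of treating versus not treating."""
    return Incremental(
        delta_cost=treated.expected_cost - untreated.expected_cost,
        deaths_averted=untreated.p_death - treated.p_death,
        amputations_averted=untreated.p_amputation - treated.p_amputation,
        dalys_averted=untreated.expected_dalys - treated.expected_dalys,
    )


def _check_unit(name: str, value) -> None:
    import numpy as np

    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")
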