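"""Patient-level microsimulation oracle and random parameter generator.

The decision tree is evaluated analytically elsewhere; this module samples
it patient by patient so the closed-form arm expectations can be checked by
brute force, and generates random-but-valid country parameter sets (uniform
within the cross-country envelopes of the reported inputs) for property
tests. Common random numbers across arms are supported (and on by default in
:func:`oracle_icer`) so incremental quantities are estimated with reduced
variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .daly import DalyConstants, daly_constants
from .parameters import (
    CostInputs,
    CountryParameters,
    GlobalAssumptions,
    validate_parameters,
)

__all__ = [
    "EmpiricalArmOutcome",
    "OracleICER",
    "simulate_cohort",
    "generate_country_params",
    "oracle_icer",
    "PARAMETER_ENVELOPE",
]

#: Uniform sampling envelope for synthetic countries: the spans of reported
#: base-case values across the 16 countries.
PARAMETER_ENVELOPE = {
    "p_cv": (0.01, 0.85),
    "p_cv_mort_untreated": (0.081, 0.1583),
    "p_ncv_mort_untreated": (0.05, 0.273),
    "av_eff_cv": (0.5643, 0.92),
    "av_eff_ncv": (0.436, 0.92),
    "p_ear_mono": (0.033, 0.19),
    "p_ear_poly": (0.033, 0.26),
    "gdp_per_capita": (385.0, 2742.0),
    "life_expectancy_remaining": (37, 45),  # integer years
}


@dataclass(frozen=True)
class EmpiricalArmOutcome:
    """Cohort means with standard errors for one simulated arm."""

    arm_label: str
    n: int
    p_death: float
    se_p_death: float
    p_amputation: float
    se_p_amputation: float
    expected_cost: float
    se_cost: float
    expected_dalys: float
    se_dalys: float


def _uniform_block(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """The five uniforms each simulated patient consumes, in fixed order."""
    return {
        "snake": rng.random(n),
        "ear": rng.random(n),
        "ear_death": rng.random(n),
        "env_death": rng.random(n),
        "amputation": rng.random(n),
    }


def _simulate_arm(
    arm: str,
    cp: CountryParameters,
    ga: GlobalAssumptions,
    ci: CostInputs,
    dc: DalyConstants,
    u: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Per-patient outcomes (died, amputated, cost, dalys) for one arm."""
    is_cv = u["snake"] < cp.p_cv
    if arm == "untreated":
        p_env = np.where(is_cv, cp.p_cv_mort_untreated, cp.p_ncv_mort_untreated)
        died = u["env_death"] < p_env
        cost = np.full(died.shape, float(ci.c_no_antivenom))
    elif arm == "treated":
        p_ear = np.where(is_cv, cp.p_ear_mono, cp.p_ear_poly)
        ear = u["ear"] < p_ear
        died_of_ear = ear & (u["ear_death"] < ga.p_ear_mort)
        p_env = np.where(
            is_cv,
            cp.p_cv_mort_untreated * (1.0 - cp.av_eff_cv),
            cp.p_ncv_mort_untreated * (1.0 - cp.av_eff_ncv),
        )
        died = died_of_ear | (~died_of_ear & (u["env_death"] < p_env))
        cost = ci.fixed_treated_cost + ear * ci.c_adv_reaction
    else:
        raise ValueError(f"arm must be 'treated' or 'untreated', got {arm!r}")

    amputated = ~died & (u["amputation"] < ga.p_disabl)
    dalys = died * dc.yll_per_death + amputated * dc.yld_per_disability
    return {"died": died, "amputated": amputated, "cost": cost, "dalys": dalys}


def _aggregate(arm: str, rec: dict[str, np.ndarray]) -> EmpiricalArmOutcome:
    n = rec["died"].size
    p_death = rec["died"].mean()
    p_amp = rec["amputated"].mean()
    return EmpiricalArmOutcome(
        arm_label=arm,
        n=n,
        p_death=float(p_death),
        se_p_death=float(np.sqrt(p_death * (1.0 - p_death) / n)),
        p_amputation=float(p_amp),
        se_p_amputation=float(np.sqrt(p_amp * (1.0 - p_amp) / n)),
        expected_cost=float(rec["cost"].mean()),
        se_cost=float(rec["cost"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        expected_dalys=float(rec["dalys"].mean()),
        se_dalys=float(rec["dalys"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
    )


def simulate_cohort(
    arm: str,
    cp: CountryParameters,
    ga: GlobalAssumptions,
    ci: CostInputs,
    dc: DalyConstants,
    n: int,
    seed: int,
) -> EmpiricalArmOutcome:
    """Simulate ``n`` patients through one arm; empirical means with SEs."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    rng = np.random.default_rng(seed)
    rec = _simulate_arm(arm, cp, ga, ci, dc, _uniform_block(rng, n))
    return _aggregate(arm, rec)


@dataclass(frozen=True)
class OracleICER:
    """Simulated ICER estimates with delta-method standard errors."""

    status: str  # "ok" | "inconclusive"
    n: int
    icer_per_daly: float
    se_icer_per_daly: float
    cost_per_death_averted: float
    se_cost_per_death: float


def _ratio_and_se(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """mean(x)/mean(y) with the first-order delta-method standard error."""
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    vx = x.var(ddof=1) / n
    vy = y.var(ddof=1) / n
    cov = np.cov(x, y, ddof=1)[0, 1] / n
    r = xbar / ybar
    var_r = (vx - 2.0 * r * cov + r * r * vy) / (ybar * ybar)
    return float(r), float(np.sqrt(max(var_r, 0.0)))


def oracle_icer(
    cp: CountryParameters,
    ga: GlobalAssumptions,
    ci: CostInputs,
    n: int,
    seed: int,
    common_random_numbers: bool = True,
) -> OracleICER:
    """Simulated ICER (per DALY and per death averted) from two cohorts.

    With common random numbers (the default) both arms reuse one uniform
    block per patient, which strongly reduces the variance of the
    incremental estimates.
    """
    dc = daly_constants(cp, ga)
    rng = np.random.default_rng(seed)
    u_t = _uniform_block(rng, n)
    u_u = u_t if common_random_numbers else _uniform_block(rng, n)
    treated = _simulate_arm("treated", cp, ga, ci, dc, u_t)
    untreated = _simulate_arm("untreated", cp, ga, ci, dc, u_u)

    delta_cost = treated["cost"] - untreated["cost"]
    dalys_averted = untreated["dalys"] - treated["dalys"]
    deaths_averted = untreated["died"].astype(float) - treated["died"].astype(float)
    if dalys_averted.mean() <= 0 or deaths_averted.mean() <= 0:
        return OracleICER("inconclusive", n, np.nan, np.nan, np.nan, np.nan)

    icer, se_icer = _ratio_and_se(delta_cost, dalys_averted)
    cpd, se_cpd = _ratio_and_se(delta_cost, deaths_averted)
    return OracleICER("ok", n, icer, se_icer, cpd, se_cpd)


def generate_country_params(
    seed: int | np.random.Generator,
    envelope: dict | None = None,
) -> CountryParameters:
    """A random, always-valid country parameter set within the envelope."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    env = dict(PARAMETER_ENVELOPE)
    if envelope:
        env.update(envelope)

    def u(name: str) -> float:
        low, high = env[name]
        return float(rng.uniform(low, high))

    lo_L, hi_L = env["life_expectancy_remaining"]
    cp = CountryParameters(
        country_id=f"synthetic_{rng.integers(1, 10**9)}",
        gdp_per_capita=u("gdp_per_capita"),
        life_expectancy_remaining=int(rng.integers(lo_L, hi_L + 1)),
        p_cv=u("p_cv"),
        p_cv_mort_untreated=u("p_cv_mort_untreated"),
        p_ncv_mort_untreated=u("p_ncv_mort_untreated"),
        av_eff_cv=u("av_eff_cv"),
        av_eff_ncv=u("av_eff_ncv"),
        p_ear_mono=u("p_ear_mono"),
        p_ear_poly=u("p_ear_poly"),
        antivenom_label="synthetic",
    )
    assert validate_parameters(cp) == []
    return cp
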