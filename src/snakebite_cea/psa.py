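"""Probabilistic sensitivity analysis (PSA).

Sixteen model inputs are sampled jointly and independently per iteration:
seven country probabilities (snake mix, untreated mortalities, two
effectiveness values, two EAR risks), EAR mortality, amputation risk, the
amputation disability weight, and the six treated-arm cost items. Beta
distributions back every probability/weight; costs are Normal truncated at
zero. Each iteration re-evaluates the deterministic decision tree, giving a
distribution of ICERs, a 2.5-97.5 percentile interval, and the probability
that the ICER falls below a willingness-to-pay (WTP) threshold.

Because only distribution families are reported for the inputs, the
parameterisation is a package choice, recorded on every spec:

* a probability with a reported (low, high) envelope and an interior base
  value gets a Beta with mean equal to the base value, with its
  concentration fitted so the 2.5/97.5% quantiles approach the envelope
  (``method="quantile_fit"``);
* when that fit is infeasible (base on or near an envelope bound, or a
  strongly asymmetric envelope) the modified-PERT construction on
  (low, base, high) is used instead (``method="pert"``);
* probabilities with no reported envelope (EAR mortality, amputation risk,
  disability weight) get a moment-matched Beta with a 25% coefficient of
  variation;
* costs get Normal(mean, 0.20 x mean) truncated at zero; the comparator
  cost is never varied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .daly import discounted_life_years
from .parameters import CostInputs, CountryParameters, GlobalAssumptions
from .tree import (
    treated_death_probability,
    untreated_death_probability,
    mixture_ear_probability,
)

__all__ = [
    "DistributionSpec",
    "PSAResult",
    "beta_from_base_and_interval",
    "beta_from_mean_cv",
    "normal_cost_spec",
    "point_mass",
    "sample",
    "default_distribution_table",
    "run_psa",
    "ceac",
    "PSA_FIELDS",
    "EFFECTIVENESS_BOUNDS_CV",
]

#: Sampling order of the 16 varied inputs (fixed so that results depend only
#: on the seed, never on evaluation order).
PSA_FIELDS = (
    "p_cv",
    "p_cv_mort_untreated",
    "p_ncv_mort_untreated",
    "av_eff_cv",
    "av_eff_ncv",
    "p_ear_mono",
    "p_ear_poly",
    "p_ear_mort",
    "p_disabl",
    "dw_amputation",
    "c_antivenom",
    "c_20wbct",
    "c_adv_reaction",
    "c_supp_care",
    "c_feed_transp",
    "c_refrg_transp",
)

#: Reported 95% bounds on carpet-viper effectiveness, by country. Countries
#: absent here fall back to the cross-country envelope (56.43-92%).
EFFECTIVENESS_BOUNDS_CV: dict[str, tuple[float, float]] = {
    "nigeria": (0.87, 0.95),
    "burkina_faso": (0.87, 0.95),
    "cameroon": (0.561, 0.95),
    "ghana": (0.561, 0.95),
    "chad": (0.0, 0.852),
    "cote_divoire": (0.55, 0.86),
    "gambia": (0.55, 0.86),
    "guinea_bissau": (0.55, 0.86),
    "liberia": (0.55, 0.86),
    "niger": (0.55, 0.86),
    "senegal": (0.55, 0.86),
    "sierra_leone": (0.55, 0.86),
    "togo": (0.55, 0.86),
}

#: Reported bounds on the elapid (non-carpet-viper) effectiveness estimate.
_EFF_NCV_BOUNDS_436 = (0.0, 0.805)

_GLOBAL_BOUNDS = {
    "p_cv": (0.01, 0.85),
    "p_cv_mort_untreated": (0.081, 0.1583),
    "p_ncv_mort_untreated": (0.05, 0.273),
    "av_eff_cv": (0.5643, 0.92),
    "av_eff_ncv": (0.436, 0.92),
    "p_ear_mono": (0.033, 0.19),
    "p_ear_poly": (0.033, 0.26),
}


@dataclass(frozen=True)
class DistributionSpec:
    """One sampled input: family, family-specific parameters, support."""

    family: str  # "beta" | "normal" | "point"
    params: dict = field(default_factory=dict)
    low: float = 0.0
    high: float = 1.0
    source_field: str = ""
    method: str = ""  # how the parameters were obtained


def beta_from_base_and_interval(base: float, low: float, high: float) -> DistributionSpec:
    """Beta spec with mean ``base``; (low, high) treated as the 95% interval.

    The concentration is fitted so the 2.5/97.5% quantiles match the
    interval as closely as a fixed-mean Beta allows (an asymmetric interval
    around the mean can only be matched approximately). If the base value
    sits on a bound or the best fit misses a bound by more than 0.05, the
    modified-PERT construction on (low, base, high) is used instead.
    """
    if not (0.0 <= low <= base <= high <= 1.0):
        raise ValueError(f"need 0 <= low <= base <= high <= 1, got {(base, low, high)}")
    if low == high:
        raise ValueError("degenerate interval: use point_mass instead")
    if base == low or base == high:
        return _pert(base, low, high)

    def misfit(log_k: float) -> float:
        k = 10.0**log_k
        a, b = base * k, (1.0 - base) * k
        q_lo, q_hi = stats.beta.ppf([0.025, 0.975], a, b)
        return (q_lo - low) ** 2 + (q_hi - high) ** 2

    res = optimize.minimize_scalar(misfit, bounds=(-1.0, 5.0), method="bounded")
    k = 10.0**res.x
    a, b = base * k, (1.0 - base) * k
    q_lo, q_hi = stats.beta.ppf([0.025, 0.975], a, b)
    if max(abs(q_lo - low), abs(q_hi - high)) > 0.05:
        return _pert(base, low, high)
    return DistributionSpec(
        family="beta",
        params={"a": float(a), "b": float(b), "loc": 0.0, "scale": 1.0},
        low=0.0,
        high=1.0,
        method="quantile_fit",
    )


def _pert(mode: float, low: float, high: float, lam: float = 4.0) -> DistributionSpec:
    """Modified-PERT Beta on (low, high) with the given mode."""
    span = high - low
    a = 1.0 + lam * (mode - low) / span
    b = 1.0 + lam * (high - mode) / span
    return DistributionSpec(
        family="beta",
        params={"a": float(a), "b": float(b), "loc": float(low), "scale": float(span)},
        low=float(low),
        high=float(high),
        method="pert",
    )


def beta_from_mean_cv(mean: float, cv: float = 0.25) -> DistributionSpec:
    """Moment-matched Beta with the given mean and coefficient of variation."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must be in (0, 1), got {mean!r}")
    var = (cv * mean) ** 2
    k = mean * (1.0 - mean) / var - 1.0
    if k <= 0:
        raise ValueError(f"cv={cv!r} too large for mean={mean!r}")
    return DistributionSpec(
        family="beta",
        params={"a": mean * k, "b": (1.0 - mean) * k, "loc": 0.0, "scale": 1.0},
        method="moment_cv",
    )


def normal_cost_spec(mean: float, sd: float | None = None) -> DistributionSpec:
    """Normal(mean, sd) truncated at 0 for a cost; default sd = 0.20 x mean."""
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean!r}")
    if sd is None:
        sd = 0.20 * mean
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd!r}")
    if sd == 0:
        return point_mass(mean)
    return DistributionSpec(
        family="normal",
        params={"mean": float(mean), "sd": float(sd)},
        low=0.0,
        high=np.inf,
        method="default_sd" ,
    )


def point_mass(value: float) -> DistributionSpec:
    return DistributionSpec(
        family="point", params={"value": float(value)}, low=value, high=value,
        method="not_varied",
    )


def sample(spec: DistributionSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw ``size`` values from a spec using the given generator."""
    if spec.family == "point":
        return np.full(size, spec.params["value"])
    if spec.family == "beta":
        z = rng.beta(spec.params["a"], spec.params["b"], size=size)
        return spec.params["loc"] + spec.params["scale"] * z
    if spec.family == "normal":
        mean, sd = spec.params["mean"], spec.params["sd"]
        # truncation at 0 via the inverse CDF, so one uniform per draw
        u = rng.uniform(stats.norm.cdf(0.0, mean, sd), 1.0, size=size)
        return stats.norm.ppf(u, mean, sd)
    raise ValueError(f"unknown family {spec.family!r}")


def _interval_spec(base: float, bounds: tuple[float, float]) -> DistributionSpec:
    """Beta for a probability with a reported envelope, clamping the base into it.

    The envelope is the span of reported base-case values across countries,
    so a country whose own base value sits on an envelope bound gets a
    moment-matched Beta centred at its base (CV 25%) rather than a
    distribution shifted into the envelope's interior.
    """
    low, high = bounds
    base = min(max(base, low), high)
    if base == low or base == high:
        return beta_from_mean_cv(base)
    return beta_from_base_and_interval(base, low, high)


def default_distribution_table(
    cp: CountryParameters,
    ga: GlobalAssumptions,
    ci: CostInputs,
    use_country_bounds: bool = True,
) -> dict[str, DistributionSpec]:
    """Distribution specs for the 16 varied inputs of one country's PSA.

    ``use_country_bounds=True`` uses the country's reported effectiveness
    interval where one exists; ``False`` uses the cross-country envelope for
    every country.
    """
    if use_country_bounds:
        eff_cv_bounds = EFFECTIVENESS_BOUNDS_CV.get(
            cp.country_id, _GLOBAL_BOUNDS["av_eff_cv"]
        )
        if cp.av_eff_ncv == cp.av_eff_cv:
            eff_ncv_bounds = eff_cv_bounds
        else:
            eff_ncv_bounds = _EFF_NCV_BOUNDS_436
    else:
        eff_cv_bounds = _GLOBAL_BOUNDS["av_eff_cv"]
        eff_ncv_bounds = _GLOBAL_BOUNDS["av_eff_ncv"]

    table = {
        "p_cv": _interval_spec(cp.p_cv, _GLOBAL_BOUNDS["p_cv"]),
        "p_cv_mort_untreated": _interval_spec(
            cp.p_cv_mort_untreated, _GLOBAL_BOUNDS["p_cv_mort_untreated"]
        ),
        "p_ncv_mort_untreated": _interval_spec(
            cp.p_ncv_mort_untreated, _GLOBAL_BOUNDS["p_ncv_mort_untreated"]
        ),
        "av_eff_cv": _interval_spec(cp.av_eff_cv, eff_cv_bounds),
        "av_eff_ncv": _interval_spec(cp.av_eff_ncv, eff_ncv_bounds),
        "p_ear_mono": _interval_spec(cp.p_ear_mono, _GLOBAL_BOUNDS["p_ear_mono"]),
        "p_ear_poly": _interval_spec(cp.p_ear_poly, _GLOBAL_BOUNDS["p_ear_poly"]),
        "p_ear_mort": beta_from_mean_cv(ga.p_ear_mort),
        "p_disabl": beta_from_mean_cv(ga.p_disabl),
        "dw_amputation": beta_from_mean_cv(ga.dw_amputation),
        "c_antivenom": normal_cost_spec(ci.c_antivenom),
        "c_20wbct": normal_cost_spec(ci.c_20wbct),
        "c_adv_reaction": normal_cost_spec(ci.c_adv_reaction),
        "c_supp_care": normal_cost_spec(ci.c_supp_care),
        "c_feed_transp": normal_cost_spec(ci.c_feed_transp),
        "c_refrg_transp": normal_cost_spec(ci.c_refrg_transp),
    }
    # record the field each spec backs
    return {
        name: DistributionSpec(
            spec.family, spec.params, spec.low, spec.high, name, spec.method
        )
        for name, spec in table.items()
    }


@dataclass(frozen=True)
class PSAResult:
    country_id: str
    n_iterations: int
    seed: int
    wtp: float
    percentile_2_5: float
    percentile_97_5: float
    prob_cost_effective: float
    icer_draws: np.ndarray | None = None


_MAX_RESAMPLE_ROUNDS = 100


def _draw_inputs(
    dists: dict[str, DistributionSpec], rng: np.random.Generator, n: int
) -> dict[str, np.ndarray]:
    """Sample all varied fields; resample any draw violating its invariants."""
    draws = {name: sample(dists[name], rng, n) for name in PSA_FIELDS}
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = np.zeros(n, dtype=bool)
        for name in PSA_FIELDS:
            x = draws[name]
            if name.startswith("c_"):
                bad |= x < 0
            else:
                bad |= (x < 0) | (x > 1)
        if not bad.any():
            return draws
        m = int(bad.sum())
        for name in PSA_FIELDS:
            draws[name][bad] = sample(dists[name], rng, m)
    raise RuntimeError("resampling cap exceeded: a distribution spec keeps "
                       "producing invalid draws")


def _icer_draws(
    cp: CountryParameters,
    ga: GlobalAssumptions,
    ci: CostInputs,
    draws: dict[str, np.ndarray],
) -> np.ndarray:
    """Vectorised deterministic pipeline over sampled inputs; inf where dominated."""
    annuity = discounted_life_years(cp.life_expectancy_remaining, ga.discount_rate)
    yll = annuity
    yld = draws["dw_amputation"] * annuity

    p_death_u = untreated_death_probability(
        draws["p_cv"], draws["p_cv_mort_untreated"], draws["p_ncv_mort_untreated"]
    )
    p_death_t = treated_death_probability(
        draws["p_cv"],
        draws["p_cv_mort_untreated"],
        draws["p_ncv_mort_untreated"],
        draws["av_eff_cv"],
        draws["av_eff_ncv"],
        draws["p_ear_mono"],
        draws["p_ear_poly"],
        draws["p_ear_mort"],
    )
    amp_u = (1.0 - p_death_u) * draws["p_disabl"]
    amp_t = (1.0 - p_death_t) * draws["p_disabl"]

    ear_mix = mixture_ear_probability(
        draws["p_cv"], draws["p_ear_mono"], draws["p_ear_poly"]
    )
    cost_t = (
        draws["c_antivenom"]
        + draws["c_20wbct"]
        + draws["c_supp_care"]
        + draws["c_feed_transp"]
        + draws["c_refrg_transp"]
        + ear_mix * draws["c_adv_reaction"]
    )
    delta_cost = cost_t - ci.c_no_antivenom

    dalys_averted = (p_death_u - p_death_t) * yll + (amp_u - amp_t) * yld
    icer = np.full_like(dalys_averted, np.inf)
    ok = dalys_averted > 0
    icer[ok] = delta_cost[ok] / dalys_averted[ok]
    return icer


def run_psa(
    cp: CountryParameters,
    ga: GlobalAssumptions,
    ci: CostInputs,
    n: int,
    seed: int,
    wtp: float | None = None,
    dists: dict[str, DistributionSpec] | None = None,
    store_draws: bool = True,
) -> PSAResult:
    """Monte Carlo PSA: n joint input draws through the deterministic tree.

    ``wtp=None`` uses the country's own GDP per capita. Fully reproducible
    from the seed; draws are taken in a fixed field order.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    if wtp is None:
        wtp = cp.gdp_per_capita
    if dists is None:
        dists = default_distribution_table(cp, ga, ci)
    missing = set(PSA_FIELDS) - set(dists)
    if missing:
        raise ValueError(f"distribution table missing fields: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    draws = _draw_inputs(dists, rng, n)
    icer = _icer_draws(cp, ga, ci, draws)

    # dominated draws carry ICER = inf; they sort to the top and only move
    # the 97.5th percentile if more than 2.5% of draws are dominated
    lo, hi = (float(q) for q in np.percentile(icer, [2.5, 97.5]))
    return PSAResult(
        country_id=cp.country_id,
        n_iterations=n,
        seed=seed,
        wtp=float(wtp),
        percentile_2_5=lo,
        percentile_97_5=hi,
        prob_cost_effective=float(np.mean(icer < wtp)),
        icer_draws=icer if store_draws else None,
    )


def ceac(
    cp: CountryParameters,
    ga: GlobalAssumptions,
    ci: CostInputs,
    n: int,
    seed: int,
    wtp_grid,
    dists: dict[str, DistributionSpec] | None = None,
) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve over a sorted WTP grid.

    All thresholds are evaluated against one shared draw set, so the curve
    is non-decreasing by construction.
    """
    wtp_grid = list(wtp_grid)
    if any(b < a for a, b in zip(wtp_grid, wtp_grid[1:])):
        raise ValueError("wtp_grid must be sorted ascending")
    result = run_psa(cp, ga, ci, n, seed, wtp=1.0, dists=dists, store_draws=True)
    icer = result.icer_draws
    return [(float(w), float(np.mean(icer < w))) for w in wtp_grid]
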