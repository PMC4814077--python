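"""Discounted life-year arithmetic (YLL per death, YLD per disability case).

Health outcomes are discounted at an annual rate r with the discrete
end-of-year annuity sum(t=1..L) (1+r)^-t = (1 - (1+r)^-L) / r, which for
r = 3% gives 22.17 discounted years at L = 37 and 24.52 at L = 45. A death
costs the full discounted remaining life expectancy; a lifelong disability
costs the disability weight times the same annuity. Costs are never
discounted (the episode lasts days); no age-weighting is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import CountryParameters, GlobalAssumptions

__all__ = ["DalyConstants", "discounted_life_years", "yll_per_death", "yld_per_case", "daly_constants"]


def discounted_life_years(life_years: float, rate: float) -> float:
    """Discounted years over ``life_years`` whole years at annual ``rate``.

    Discrete end-of-year annuity: (1 - (1+r)^-L) / r, with the r -> 0 limit L.
    """
    if life_years < 0:
        raise ValueError(f"life_years must be >= 0, got {life_years!r}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate!r}")
    if rate == 0:
        return float(life_years)
    # -expm1(-L*log1p(r))/r == (1-(1+r)^-L)/r, stable as r -> 0
    return -math.expm1(-life_years * math.log1p(rate)) / rate


def yll_per_death(life_years: float, rate: float) -> float:
    """Years of life lost per death: the discounted remaining life expectancy."""
    return discounted_life_years(life_years, rate)


def yld_per_case(disability_weight: float, life_years: float, rate: float) -> float:
    """Years lived with disability per surviving case with lifelong sequela."""
    if not 0.0 <= disability_weight <= 1.0:
        raise ValueError(
            f"disability_weight must be in [0, 1], got {disability_weight!r}"
        )
    return disability_weight * discounted_life_years(life_years, rate)


@dataclass(frozen=True)
class DalyConstants:
    """Per-country discounted DALY constants at the rate they were built with."""

    country_id: str
    yll_per_death: float
    yld_per_disability: float
    discount_rate: float


def daly_constants(
    cp: CountryParameters,
    ga: GlobalAssumptions,
    disability_weight: float | None = None,
) -> DalyConstants:
    """Build the country's DALY constants (default disability: amputation)."""
    dw = ga.dw_amputation if disability_weight is None else disability_weight
    L = cp.life_expectancy_remaining
    return DalyConstants(
        country_id=cp.country_id,
        yll_per_death=yll_per_death(L, ga.discount_rate),
        yld_per_disability=yld_per_case(dw, L, ga.discount_rate),
        discount_rate=ga.discount_rate,
    )
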