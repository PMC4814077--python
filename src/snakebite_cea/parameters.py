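"""Model parameters: country inputs, global assumptions, and the cost bundle.

The analysis covers 16 West African countries. Each country contributes a row
of epidemiological inputs (proportion of envenoming due to carpet viper,
untreated case fatality by snake type, antivenom effectiveness, early
adverse reaction (EAR) risks, remaining life expectancy at the mean age of
bite, GDP per capita used as the willingness-to-pay threshold). Cross-country
constants (EAR mortality, amputation risk, disability weights, discount
rate) and the per-patient cost bundle are shared by all countries.

Countries without a product-specific EAR estimate carry the median EAR risk
of 4.3%; countries without their own effectiveness study carry the pooled
meta-analytic effectiveness of 75%. Liberia and Sierra Leone use a 1%
carpet-viper proportion in the base case (their reported 0% is analysed as a
separate scenario).
"""

from __future__ import annotations

import csv
import dataclasses
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "CountryParameters",
    "GlobalAssumptions",
    "CostInputs",
    "ParameterError",
    "load_country_table",
    "write_country_table",
    "load_assumptions",
    "validate_parameters",
    "COUNTRY_IDS",
]

#: Canonical row order of the packaged table.
COUNTRY_IDS = (
    "benin",
    "burkina_faso",
    "cameroon",
    "chad",
    "cote_divoire",
    "gambia",
    "ghana",
    "guinea_bissau",
    "guinea_conakry",
    "liberia",
    "mali",
    "niger",
    "nigeria",
    "senegal",
    "sierra_leone",
    "togo",
)

#: Countries whose non-carpet-viper effectiveness defaults to the
#: Antivipmyn elapid estimate (43.6%) rather than the carpet-viper value.
_NCV_EFF_DEFAULT_436 = {"benin", "guinea_conakry", "guinea_bissau"}

_COLUMNS = (
    "country",
    "gdp_per_capita",
    "life_expectancy",
    "p_cv",
    "p_cv_mort",
    "p_ncv_mort",
    "av_eff_cv",
    "av_eff_ncv",
    "p_ear_mono",
    "p_ear_poly",
    "antivenom_label",
)


class ParameterError(ValueError):
    """Raised for schema or invariant violations in model inputs."""


@dataclass(frozen=True)
class CountryParameters:
    """One country's model inputs.

    All probabilities and effectiveness values are fractions in [0, 1];
    ``life_expectancy_remaining`` is the integer remaining life expectancy
    (years) at the mean age of bite; ``gdp_per_capita`` is USD per person
    per year and doubles as the willingness-to-pay threshold per DALY.
    """

    country_id: str
    gdp_per_capita: float
    life_expectancy_remaining: int
    p_cv: float
    p_cv_mort_untreated: float
    p_ncv_mort_untreated: float
    av_eff_cv: float
    av_eff_ncv: float
    p_ear_mono: float
    p_ear_poly: float
    antivenom_label: str = "meta-analytic"

    def replace(self, **overrides) -> "CountryParameters":
        return dataclasses.replace(self, **overrides)


@dataclass(frozen=True)
class GlobalAssumptions:
    """Constants shared across the 16 country models."""

    p_ear_mort: float = 0.01
    p_disabl: float = 0.03
    dw_amputation: float = 0.102
    discount_rate: float = 0.03
    dw_blindness: float = 0.552
    p_blindness: float = 0.0001
    dw_ptsd: float = 0.105
    p_ptsd: float = 0.20
    adrenaline_x: float = 0.40

    def replace(self, **overrides) -> "GlobalAssumptions":
        return dataclasses.replace(self, **overrides)


@dataclass(frozen=True)
class CostInputs:
    """Per-patient costs in USD for the treated arm (comparator cost separate).

    ``c_adv_reaction`` is incurred only on EAR branches; ``c_no_antivenom``
    is the comparator-arm cost (zero in the base case, 65.63 in the
    basic-care scenario).
    """

    c_antivenom: float = 153.0
    c_20wbct: float = 3.125
    c_adv_reaction: float = 1.875
    c_supp_care: float = 18.75
    c_feed_transp: float = 43.75
    c_refrg_transp: float = 18.75
    c_no_antivenom: float = 0.0

    def replace(self, **overrides) -> "CostInputs":
        return dataclasses.replace(self, **overrides)

    @property
    def fixed_treated_cost(self) -> float:
        """Cost incurred by every treated patient, EAR or not."""
        return (
            self.c_antivenom
            + self.c_20wbct
            + self.c_supp_care
            + self.c_feed_transp
            + self.c_refrg_transp
        )


def _probability_fields(cp: CountryParameters) -> dict:
    return {
        "p_cv": cp.p_cv,
        "p_cv_mort_untreated": cp.p_cv_mort_untreated,
        "p_ncv_mort_untreated": cp.p_ncv_mort_untreated,
        "av_eff_cv": cp.av_eff_cv,
        "av_eff_ncv": cp.av_eff_ncv,
        "p_ear_mono": cp.p_ear_mono,
        "p_ear_poly": cp.p_ear_poly,
    }


def validate_parameters(
    cp: CountryParameters,
    ga: GlobalAssumptions | None = None,
    ci: CostInputs | None = None,
) -> list[str]:
    """Return a list of invariant violations (empty iff everything is valid).

    Violations are returned as data rather than raised so that callers can
    collect all problems in one pass; each entry names the offending field
    and bound.
    """
    violations: list[str] = []
    for name, value in _probability_fields(cp).items():
        if not 0.0 <= value <= 1.0:
            violations.append(f"{cp.country_id}: {name}={value!r} outside [0, 1]")
    if not 30 <= cp.life_expectancy_remaining <= 50:
        violations.append(
            f"{cp.country_id}: life_expectancy_remaining="
            f"{cp.life_expectancy_remaining!r} outside [30, 50]"
        )
    if not cp.gdp_per_capita > 0:
        violations.append(f"{cp.country_id}: gdp_per_capita must be > 0")

    if ga is not None:
        for name in (
            "p_ear_mort",
            "p_disabl",
            "dw_amputation",
            "dw_blindness",
            "p_blindness",
            "dw_ptsd",
            "p_ptsd",
            "adrenaline_x",
        ):
            value = getattr(ga, name)
            if not 0.0 <= value <= 1.0:
                violations.append(f"{name}={value!r} outside [0, 1]")
        if not 0.0 <= ga.discount_rate <= 0.10:
            violations.append(f"discount_rate={ga.discount_rate!r} outside [0, 0.10]")

    if ci is not None:
        for field in dataclasses.fields(ci):
            value = getattr(ci, field.name)
            if value < 0:
                violations.append(f"{field.name}={value!r} must be >= 0")

    return violations


def _parse_row(row: dict, line: int) -> CountryParameters:
    def number(col: str) -> float:
        raw = (row.get(col) or "").strip()
        if raw == "":
            raise ParameterError(f"row {line}: missing value in column {col!r}")
        try:
            return float(raw)
        except ValueError as exc:
            raise ParameterError(
                f"row {line}: column {col!r} is not numeric: {raw!r}"
            ) from exc

    country = (row.get("country") or "").strip().lower()
    if not country:
        raise ParameterError(f"row {line}: missing country id")

    raw_ncv_eff = (row.get("av_eff_ncv") or "").strip()
    av_eff_cv = number("av_eff_cv")
    if raw_ncv_eff == "":
        av_eff_ncv = 0.436 if country in _NCV_EFF_DEFAULT_436 else av_eff_cv
    else:
        av_eff_ncv = number("av_eff_ncv")

    life_exp = number("life_expectancy")
    if life_exp != int(life_exp):
        raise ParameterError(
            f"row {line}: life_expectancy must be an integer, got {life_exp!r}"
        )

    return CountryParameters(
        country_id=country,
        gdp_per_capita=number("gdp_per_capita"),
        life_expectancy_remaining=int(life_exp),
        p_cv=number("p_cv"),
        p_cv_mort_untreated=number("p_cv_mort"),
        p_ncv_mort_untreated=number("p_ncv_mort"),
        av_eff_cv=av_eff_cv,
        av_eff_ncv=av_eff_ncv,
        p_ear_mono=number("p_ear_mono"),
        p_ear_poly=number("p_ear_poly"),
        antivenom_label=(row.get("antivenom_label") or "meta-analytic").strip(),
    )


def load_country_table(path: str | Path | None = None) -> list[CountryParameters]:
    """Load and validate a country parameter table.

    With ``path=None`` the packaged 16-country table is returned. The CSV
    schema is ``country,gdp_per_capita,life_expectancy,p_cv,p_cv_mort,
    p_ncv_mort,av_eff_cv,av_eff_ncv,p_ear_mono,p_ear_poly,antivenom_label``;
    a blank ``av_eff_ncv`` falls back to the country's documented default.
    Unknown columns are rejected; any invariant violation raises
    :class:`ParameterError`.
    """
    if path is None:
        text = (
            resources.files("snakebite_cea").joinpath("data/countries.csv").read_text()
        )
    else:
        text = Path(path).read_text(encoding="utf-8")

    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        raise ParameterError("empty table: no header row")
    unknown = set(reader.fieldnames) - set(_COLUMNS)
    if unknown:
        raise ParameterError(f"unknown columns: {sorted(unknown)}")
    required = set(_COLUMNS) - {"av_eff_ncv", "antivenom_label"}
    missing = required - set(reader.fieldnames)
    if missing:
        raise ParameterError(f"missing columns: {sorted(missing)}")

    countries = [_parse_row(row, line) for line, row in enumerate(reader, start=2)]

    problems: list[str] = []
    for cp in countries:
        problems.extend(validate_parameters(cp))
    if problems:
        raise ParameterError("; ".join(problems))

    if path is None and tuple(cp.country_id for cp in countries) != COUNTRY_IDS:
        raise ParameterError("packaged table does not list the 16 expected countries")
    return countries


def write_country_table(countries: Iterable[CountryParameters], path: str | Path) -> None:
    """Write countries back out in the packaged CSV schema (round-trip safe)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for cp in countries:
            writer.writerow(
                [
                    cp.country_id,
                    repr(cp.gdp_per_capita),
                    cp.life_expectancy_remaining,
                    repr(cp.p_cv),
                    repr(cp.p_cv_mort_untreated),
                    repr(cp.p_ncv_mort_untreated),
                    repr(cp.av_eff_cv),
                    repr(cp.av_eff_ncv),
                    repr(cp.p_ear_mono),
                    repr(cp.p_ear_poly),
                    cp.antivenom_label,
                ]
            )


def load_assumptions(
    path: str | Path | None = None,
) -> tuple[GlobalAssumptions, CostInputs]:
    """Load global assumptions and the cost bundle from YAML.

    ``path=None`` loads the packaged defaults. User files may override any
    subset of fields; unknown keys are rejected.
    """
    if path is None:
        text = (
            resources.files("snakebite_cea")
            .joinpath("data/assumptions.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text) or {}

    ga_fields = {f.name for f in dataclasses.fields(GlobalAssumptions)}
    ci_fields = {f.name for f in dataclasses.fields(CostInputs)}
    ga_doc = doc.get("global_assumptions", {}) or {}
    ci_doc = doc.get("cost_inputs", {}) or {}
    unknown = (set(ga_doc) - ga_fields) | (set(ci_doc) - ci_fields)
    if unknown:
        raise ParameterError(f"unknown assumption keys: {sorted(unknown)}")

    ga = GlobalAssumptions(**ga_doc)
    ci = CostInputs(**ci_doc)
    problems = validate_parameters(_DUMMY_COUNTRY, ga, ci)
    if problems:
        raise ParameterError("; ".join(problems))
    return ga, ci


# Sentinel country used only to drive the GA/CI part of validate_parameters.
_DUMMY_COUNTRY = CountryParameters(
    country_id="_sentinel",
    gdp_per_capita=1.0,
    life_expectancy_remaining=40,
    p_cv=0.5,
    p_cv_mort_untreated=0.1,
    p_ncv_mort_untreated=0.1,
    av_eff_cv=0.5,
    av_eff_ncv=0.5,
    p_ear_mono=0.05,
    p_ear_poly=0.05,
)
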