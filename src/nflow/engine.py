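"""Declarative flux evaluation: activity data x parameters -> flux records.

Each flux is declared as a sum of products

    value = sum_k  amount(activity_k, year) * parameter_k * multiplier_k

with units reduced to Gg N y-1 through the declared conversion table
(:mod:`nflow.units`). This sum-of-products grammar expresses every flux form
used in urban N budgets: fuel consumption x emission factor, product mass x N
content, population x per-capita excretion, area x fixation rate. The grammar
is linear by construction; saturating or threshold processes are outside its
scope.

The evaluated flux inherits the *worst* reliability grade among its terms'
activities and parameters, which keeps the Monte Carlo uncertainty classing
conservative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping

import pandas as pd

from . import compartments, units
from .errors import ConfigurationError, DomainError, NFlowError
from .grades import ReliabilityGrade, worst_grade
from .network import SPECIES, FluxRecord

if TYPE_CHECKING:  # pragma: no cover
    from .scenario import CityScenario


@dataclass(frozen=True)
class ActivityRecord:
    """One measured activity level (e.g. coal consumption) in one year."""

    year: int
    subsystem: str
    item: str
    amount: float
    unit: str
    grade: ReliabilityGrade

    def __post_init__(self):
        if self.amount < 0:
            raise ValueError(f"activity amount must be nonnegative ({self.item!r})")
        object.__setattr__(self, "grade", ReliabilityGrade.coerce(self.grade))
        object.__setattr__(self, "year", int(self.year))


@dataclass(frozen=True)
class ParameterRecord:
    """One conversion parameter (N content, emission factor, rate)."""

    name: str
    value: float
    unit: str
    grade: ReliabilityGrade

    def __post_init__(self):
        if self.value < 0:
            raise ValueError(f"parameter value must be nonnegative ({self.name!r})")
        object.__setattr__(self, "grade", ReliabilityGrade.coerce(self.grade))


@dataclass(frozen=True)
class FluxTerm:
    activity: str
    parameter: str
    multiplier: float = 1.0


@dataclass(frozen=True)
class FluxDefinition:
    """Directed flux declared as a sum of activity x parameter terms."""

    label: str
    source: str
    target: str
    species: str = "total_N"
    terms: tuple[FluxTerm, ...] = ()

    def __post_init__(self):
        compartments.get(self.source)
        compartments.get(self.target)
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        object.__setattr__(self, "terms", tuple(self.terms))


# ---------------------------------------------------------------------------
# lookup helpers: accept DataFrames or prebuilt dicts


def activity_lookup(
    activities: "pd.DataFrame | Mapping",
) -> Mapping[tuple[int, str], tuple[float, str, ReliabilityGrade]]:
    """Index activities by (year, item) -> (amount, unit, grade)."""
    if isinstance(activities, Mapping):
        return activities
    out: dict[tuple[int, str], tuple[float, str, ReliabilityGrade]] = {}
    for row in activities.itertuples(index=False):
        key = (int(row.year), row.item)
        if key in out:
            raise ConfigurationError(
                f"duplicate activity item {row.item!r} in year {row.year}"
            )
        out[key] = (float(row.amount), row.unit, ReliabilityGrade.coerce(row.grade))
    return out


def parameter_lookup(
    parameters: "pd.DataFrame | Mapping",
) -> Mapping[str, tuple[float, str, ReliabilityGrade]]:
    """Index parameters by name -> (value, unit, grade)."""
    if isinstance(parameters, Mapping):
        return parameters
    out: dict[str, tuple[float, str, ReliabilityGrade]] = {}
    for row in parameters.itertuples(index=False):
        if row.name in out:
            raise ConfigurationError(f"duplicate parameter name {row.name!r}")
        out[row.name] = (float(row.value), row.unit, ReliabilityGrade.coerce(row.grade))
    return out


def evaluate_flux(
    defn: FluxDefinition,
    activities,
    parameters,
    year: int,
) -> FluxRecord:
    """Evaluate one flux definition for one year.

    Unresolved activity/parameter references raise
    :class:`~nflow.errors.ConfigurationError`; incompatible units raise
    :class:`~nflow.errors.UnitError` naming the term.
    """
    acts = activity_lookup(activities)
    pars = parameter_lookup(parameters)
    total = 0.0
    grades: list[ReliabilityGrade] = []
    for term in defn.terms:
        try:
            amount, a_unit, a_grade = acts[(year, term.activity)]
        except KeyError:
            raise ConfigurationError(
                f"flux {defn.label!r}: activity {term.activity!r} not found for "
                f"year {year}"
            ) from None
        try:
            value, p_unit, p_grade = pars[term.parameter]
        except KeyError:
            raise ConfigurationError(
                f"flux {defn.label!r}: parameter {term.parameter!r} not found"
            ) from None
        total += units.term_to_gg(amount, a_unit, value, p_unit) * term.multiplier
        grades.extend((a_grade, p_grade))
    grade = worst_grade(grades) if grades else ReliabilityGrade.HIGH
    return FluxRecord(
        source=defn.source,
        target=defn.target,
        year=year,
        value=total,
        species=defn.species,
        grade=grade,
        label=defn.label,
    )


def evaluate_scenario(scenario: "CityScenario") -> list[FluxRecord]:
    """Evaluate every flux definition for every year with activities present.

    Deterministic given the scenario. Errors are re-raised with the
    (definition, year) context attached.
    """
    acts = activity_lookup(scenario.activities)
    pars = parameter_lookup(scenario.parameters)
    years = sorted({y for (y, _item) in acts})
    records: list[FluxRecord] = []
    for defn in scenario.definitions:
        for year in years:
            if not all((year, t.activity) in acts for t in defn.terms):
                continue
            try:
                records.append(evaluate_flux(defn, acts, pars, year))
            except NFlowError as exc:
                raise type(exc)(
                    f"while evaluating flux {defn.label!r} for year {year}: {exc}"
                ) from exc
    return records


def input_intensity(flux_value_gg: float, area_km2: float) -> float:
    """Areal input intensity in kg N ha-1 y-1 of a city-level flux.

    ``flux_value_gg`` is in Gg N y-1; ``area_km2`` must be positive
    (1 km2 = 100 ha, 1 Gg = 1e6 kg).
    """
    if area_km2 <= 0:
        raise DomainError(f"area must be positive, got {area_km2!r} km2")
    return flux_value_gg * 1e6 / (area_km2 * 100.0)
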