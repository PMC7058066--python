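"""Directed N-flux network and its mass-balance ledger.

Fluxes are stored as nonnegative magnitudes on directed edges between
compartments; a bidirectional exchange is two separate records. For any
compartment and year the budget identity

    accumulation = sum(inputs) - sum(outputs)

defines the stock change, and the system-level balance counts only
boundary-crossing flows (external <-> within-boundary), so that internal
recycling cancels out of the city totals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

import pandas as pd

from . import compartments
from .errors import DuplicateFluxError, UnknownCompartmentError
from .grades import ReliabilityGrade

logger = logging.getLogger(__name__)

#: Recognized nitrogen species labels.
SPECIES = (
    "total_N",
    "NOx",
    "NH3",
    "N2O",
    "N2",
    "organic_N",
    "NO3_NH4",
    "product_N",
)


@dataclass(frozen=True)
class FluxRecord:
    """One directed N flux (Gg N y-1) between two compartments in one year."""

    source: str
    target: str
    year: int
    value: float
    species: str = "total_N"
    grade: ReliabilityGrade = ReliabilityGrade.MODERATE
    label: str = ""

    def __post_init__(self):
        if self.value < 0:
            raise ValueError(
                f"flux value must be nonnegative, got {self.value!r} for "
                f"{self.source}->{self.target} ({self.label!r})"
            )
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; known: {SPECIES}")
        object.__setattr__(self, "grade", ReliabilityGrade.coerce(self.grade))
        object.__setattr__(self, "year", int(self.year))

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.source, self.target, self.year, self.label)


class Balance(NamedTuple):
    inputs: float
    outputs: float
    accumulation: float


@dataclass(frozen=True)
class BalanceLedger:
    """Per-(compartment, year) inputs, outputs and accumulation, plus system totals.

    ``frame`` has columns compartment, year, inputs, outputs, accumulation;
    ``system`` has one row per year restricted to boundary-crossing flows.
    The defining identity accumulation == inputs - outputs holds exactly by
    construction. A backref to the source network is kept so fate-channel
    classification can reach the underlying records.
    """

    frame: pd.DataFrame
    system: pd.DataFrame
    network: "Network" = field(repr=False, compare=False, default=None)

    def balance(self, compartment: str, year: int) -> Balance:
        rows = self.frame[
            (self.frame["compartment"] == compartment) & (self.frame["year"] == year)
        ]
        if rows.empty:
            return Balance(0.0, 0.0, 0.0)
        r = rows.iloc[0]
        return Balance(float(r["inputs"]), float(r["outputs"]), float(r["accumulation"]))

    def system_balance(self, year: int) -> Balance:
        rows = self.system[self.system["year"] == year]
        if rows.empty:
            return Balance(0.0, 0.0, 0.0)
        r = rows.iloc[0]
        return Balance(float(r["inputs"]), float(r["outputs"]), float(r["accumulation"]))


class Network:
    """Queryable collection of :class:`FluxRecord` with balance operations."""

    def __init__(self, records: Iterable[FluxRecord] = ()):
        records = tuple(records)
        seen: set[tuple] = set()
        for rec in records:
            for cid in (rec.source, rec.target):
                if cid not in compartments.REGISTRY:
                    raise UnknownCompartmentError(
                        f"flux record {rec.label!r} ({rec.source}->{rec.target}, "
                        f"{rec.year}) references unknown compartment {cid!r}"
                    )
            if rec.key in seen:
                raise DuplicateFluxError(
                    f"duplicate flux record key (source={rec.source}, "
                    f"target={rec.target}, year={rec.year}, label={rec.label!r})"
                )
            seen.add(rec.key)
        self._records = records

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[FluxRecord]:
        return iter(self._records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return sorted(self._records, key=lambda r: r.key) == sorted(
            other._records, key=lambda r: r.key
        )

    @property
    def records(self) -> tuple[FluxRecord, ...]:
        return self._records

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({r.year for r in self._records}))

    @property
    def compartments_present(self) -> tuple[str, ...]:
        ids = {r.source for r in self._records} | {r.target for r in self._records}
        return tuple(sorted(ids))

    # -- queries ------------------------------------------------------------
    def filter(
        self,
        year: int | None = None,
        source: str | None = None,
        target: str | None = None,
        species: str | None = None,
        label: str | None = None,
    ) -> "Network":
        def keep(r: FluxRecord) -> bool:
            return (
                (year is None or r.year == year)
                and (source is None or r.source == source)
                and (target is None or r.target == target)
                and (species is None or r.species == species)
                and (label is None or r.label == label)
            )

        return Network(r for r in self._records if keep(r))

    def total(self, **kwargs) -> float:
        return sum(r.value for r in self.filter(**kwargs))

    def labelled(self, label: str, year: int | None = None) -> float:
        """Sum of fluxes carrying ``label`` (optionally in one year)."""
        return sum(
            r.value
            for r in self._records
            if r.label == label and (year is None or r.year == year)
        )

    # -- balances -----------------------------------------------------------
    def balance(self, compartment: str, year: int) -> Balance:
        """Eq.-1 budget of one compartment in one year."""
        compartments.get(compartment)
        inputs = sum(
            r.value for r in self._records if r.target == compartment and r.year == year
        )
        outputs = sum(
            r.value for r in self._records if r.source == compartment and r.year == year
        )
        if inputs == 0.0 and outputs == 0.0:
            logger.warning(
                "compartment %r has no incident fluxes in year %s", compartment, year
            )
        return Balance(inputs, outputs, inputs - outputs)

    def system_balance(self, year: int) -> Balance:
        """City-level budget: boundary-crossing flows only."""
        inputs = sum(
            r.value
            for r in self._records
            if r.year == year
            and not compartments.is_internal(r.source)
            and compartments.is_internal(r.target)
        )
        outputs = sum(
            r.value
            for r in self._records
            if r.year == year
            and compartments.is_internal(r.source)
            and not compartments.is_internal(r.target)
        )
        return Balance(inputs, outputs, inputs - outputs)

    def group_aggregate(self, year: int) -> dict[str, Balance]:
        """Process-group budgets; intra-group fluxes cancel."""
        out: dict[str, Balance] = {}
        for group, members in compartments.GROUP_MEMBERS.items():
            mset = set(members)
            inputs = sum(
                r.value
                for r in self._records
                if r.year == year and r.target in mset and r.source not in mset
            )
            outputs = sum(
                r.value
                for r in self._records
                if r.year == year and r.source in mset and r.target not in mset
            )
            out[group] = Balance(inputs, outputs, inputs - outputs)
        return out

    def ledger(self) -> BalanceLedger:
        rows = []
        for year in self.years:
            for cid in compartments.SUBSYSTEMS:
                inputs = sum(
                    r.value for r in self._records if r.target == cid and r.year == year
                )
                outputs = sum(
                    r.value for r in self._records if r.source == cid and r.year == year
                )
                rows.append(
                    {
                        "compartment": cid,
                        "year": year,
                        "inputs": inputs,
                        "outputs": outputs,
                        "accumulation": inputs - outputs,
                    }
                )
        sys_rows = []
        for year in self.years:
            b = self.system_balance(year)
            sys_rows.append(
                {
                    "year": year,
                    "inputs": b.inputs,
                    "outputs": b.outputs,
                    "accumulation": b.accumulation,
                }
            )
        cols = ["compartment", "year", "inputs", "outputs", "accumulation"]
        frame = pd.DataFrame(rows, columns=cols)
        system = pd.DataFrame(sys_rows, columns=cols[1:])
        return BalanceLedger(frame=frame, system=system, network=self)

    # -- serialization ------------------------------------------------------
    _CSV_COLUMNS = ("source", "target", "year", "value_GgN", "species", "grade", "label")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": r.source,
                    "target": r.target,
                    "year": r.year,
                    "value_GgN": r.value,
                    "species": r.species,
                    "grade": r.grade.value,
                    "label": r.label,
                }
                for r in self._records
            ],
            columns=list(self._CSV_COLUMNS),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Network":
        missing = set(cls._CSV_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"flux table is missing columns {sorted(missing)}")
        return cls(
            FluxRecord(
                source=row.source,
                target=row.target,
                year=int(row.year),
                value=float(row.value_GgN),
                species=row.species,
                grade=ReliabilityGrade.coerce(row.grade),
                label="" if pd.isna(row.label) else str(row.label),
            )
            for row in frame.itertuples(index=False)
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Network":
        return cls.from_frame(
            pd.read_csv(
                path, keep_default_na=False, na_values=[], float_precision="round_trip"
            )
        )

    def to_sankey(self, year: int) -> dict:
        """Node/link JSON document for Sankey plotting tools."""
        sub = self.filter(year=year)
        node_ids = list(sub.compartments_present)
        return {
            "year": year,
            "nodes": [
                {"id": cid, "group": compartments.get(cid).group} for cid in node_ids
            ],
            "links": [
                {
                    "source": r.source,
                    "target": r.target,
                    "value": r.value,
                    "species": r.species,
                    "label": r.label,
                }
                for r in sub
            ],
        }

    def to_sankey_json(self, path: str | Path, year: int) -> None:
        Path(path).write_text(json.dumps(self.to_sankey(year), indent=2))


def build_network(fluxes: Iterable[FluxRecord]) -> Network:
    """Validate and index a collection of flux records."""
    return Network(fluxes)
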