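"""Derived indicators of the urban N budget.

Creation partitioning (BNF / Haber-Bosch / fossil-fuel fixation), percentage
shares, whole-system fate fractions, nitrogen use efficiency, excreta
recycling ratios, species-resolved environmental load series and life-cycle
chain traces.

Percentages follow the reporting convention of urban budget studies: rounded
half-away-from-zero, one decimal by default (zero where integers are
customary). Raw unrounded values are always retained alongside because
several published percentages differ from recomputation only through upstream
rounding of the fluxes themselves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

from . import compartments
from .errors import ConfigurationError, ConsistencyError, DomainError
from .network import BalanceLedger, Network

logger = logging.getLogger(__name__)

#: Subsystems counted as the terrestrial accumulation pool.
TERRESTRIAL_SUBSYSTEMS = (
    "farmland",
    "livestock",
    "forest",
    "aquaculture",
    "human",
    "ground_water",
    "urban_green",
)


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (5 always rounds up in magnitude)."""
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def share_of(part: float, whole: float, decimals: int = 1) -> float:
    """Percentage ``100 * part / whole`` rounded half-away-from-zero."""
    if whole <= 0:
        raise DomainError(f"whole must be positive, got {whole!r}")
    if part < 0:
        raise DomainError(f"part must be nonnegative, got {part!r}")
    return round_half_away(100.0 * part / whole, decimals)


# ---------------------------------------------------------------------------
# creation partition


@dataclass(frozen=True)
class CreationPartition:
    """New-Nr creation split (Gg N y-1): biological, industrial, combustion."""

    bnf: float
    hbnf: float
    fossil_fixation: float
    natural_bnf: float = 0.0

    @property
    def total_creation(self) -> float:
        return self.bnf + self.hbnf + self.fossil_fixation

    @property
    def anthropogenic_total(self) -> float:
        """Creation excluding natural BNF (agricultural BNF counts as anthropogenic)."""
        return self.total_creation - self.natural_bnf


#: flux labels classed as creation channels (fixture and generator vocabulary)
CREATION_LABELS = {
    "bnf": ("abnf", "nbnf", "bnf"),
    "natural_bnf": ("nbnf",),
    "hbnf": ("hbnf",),
    "fossil_fixation": ("fossil_fuel_fixation",),
}


def creation_partition(network: Network, year: int) -> CreationPartition:
    """Partition fixation-source inflows by creation channel."""
    def total(labels) -> float:
        return sum(
            r.value
            for r in network
            if r.year == year and r.source == "fixation_source" and r.label in labels
        )

    return CreationPartition(
        bnf=total(CREATION_LABELS["bnf"]),
        hbnf=total(CREATION_LABELS["hbnf"]),
        fossil_fixation=total(CREATION_LABELS["fossil_fixation"]),
        natural_bnf=total(CREATION_LABELS["natural_bnf"]),
    )


# ---------------------------------------------------------------------------
# fate fractions


@dataclass(frozen=True)
class FateFractions:
    """Where one year's total Nr input ends up, as % of total input.

    The six components close to 100 within +-0.2 (rounding); ``raw`` carries
    the unrounded values.
    """

    denitrified_n2: float
    atmospheric_transfer: float
    surface_water_transfer: float
    trade_output: float
    terrestrial_accumulation: float
    residual: float
    raw: Mapping[str, float]

    def as_dict(self) -> dict[str, float]:
        return {
            "denitrified_n2": self.denitrified_n2,
            "atmospheric_transfer": self.atmospheric_transfer,
            "surface_water_transfer": self.surface_water_transfer,
            "trade_output": self.trade_output,
            "terrestrial_accumulation": self.terrestrial_accumulation,
            "residual": self.residual,
        }


def _as_network(obj: "Network | BalanceLedger") -> Network:
    if isinstance(obj, Network):
        return obj
    if isinstance(obj, BalanceLedger):
        if obj.network is None:
            raise ConfigurationError(
                "this BalanceLedger carries no network backref; fate channels "
                "cannot be classified from totals alone"
            )
        return obj.network
    raise TypeError(f"expected Network or BalanceLedger, got {type(obj).__name__}")


def fate_fractions(obj: "Network | BalanceLedger", year: int, decimals: int = 1) -> FateFractions:
    """Life-cycle fate of one year's Nr input.

    Channels: denitrification to inert N2 (boundary outflows with species N2),
    reactive atmospheric transfer to surrounding regions, riverine transfer to
    the ocean, trade outputs, and accumulation in the terrestrial subsystems;
    the residual closes the budget (treatment/atmosphere stock drift and
    rounding).
    """
    network = _as_network(obj)
    total_in = network.system_balance(year).inputs
    if total_in <= 0:
        raise DomainError(f"total Nr input in {year} is not positive")

    boundary_out = [
        r
        for r in network
        if r.year == year
        and compartments.is_internal(r.source)
        and not compartments.is_internal(r.target)
    ]
    n2 = sum(r.value for r in boundary_out if r.species == "N2")
    atm = sum(
        r.value
        for r in boundary_out
        if r.target == "surrounding_atmosphere" and r.species != "N2"
    )
    sw = sum(r.value for r in boundary_out if r.target == "ocean")
    trade = sum(r.value for r in boundary_out if r.target == "world_trade")
    terrestrial = sum(
        network.balance(c, year).accumulation for c in TERRESTRIAL_SUBSYSTEMS
    )
    raw = {
        "denitrified_n2": 100.0 * n2 / total_in,
        "atmospheric_transfer": 100.0 * atm / total_in,
        "surface_water_transfer": 100.0 * sw / total_in,
        "trade_output": 100.0 * trade / total_in,
        "terrestrial_accumulation": 100.0 * terrestrial / total_in,
    }
    raw["residual"] = 100.0 - sum(raw.values())
    rounded = {k: round_half_away(v, decimals) for k, v in raw.items()}
    return FateFractions(**rounded, raw=raw)


def environment_share_of_outputs(network: Network, year: int, decimals: int = 1) -> float:
    """% of total outputs discharged as Nr to the shared environment.

    Counts reactive transfer to the surrounding atmosphere plus riverine
    export to the ocean; inert N2 and traded products are excluded.
    """
    b = network.system_balance(year)
    if b.outputs <= 0:
        raise DomainError(f"total outputs in {year} are not positive")
    env = sum(
        r.value
        for r in network
        if r.year == year
        and compartments.is_internal(r.source)
        and (
            (r.target == "surrounding_atmosphere" and r.species != "N2")
            or r.target == "ocean"
        )
    )
    return share_of(env, b.outputs, decimals)


# ---------------------------------------------------------------------------
# efficiency and recycling ratios


def nue(harvest_n: float, inputs_n: float) -> float:
    """Nitrogen use efficiency: harvested crop N over total N inputs to farmland."""
    if inputs_n <= 0:
        raise DomainError(f"farmland N inputs must be positive, got {inputs_n!r}")
    ratio = harvest_n / inputs_n
    if ratio > 1.0:
        warnings.warn(
            f"NUE {ratio:.2f} exceeds 1: harvest draws down the soil N stock "
            "(soil mining)",
            stacklevel=2,
        )
    return ratio


def recycling_ratio(excreta_to_farmland: float, excreta_total: float) -> float:
    """Fraction of livestock or human excreta N returned to farmland."""
    if excreta_total <= 0:
        raise DomainError(f"total excreta must be positive, got {excreta_total!r}")
    if excreta_to_farmland < 0:
        raise DomainError("returned excreta must be nonnegative")
    if excreta_to_farmland > excreta_total * (1 + 1e-12):
        raise ConsistencyError(
            f"excreta returned to farmland ({excreta_to_farmland}) exceeds the "
            f"total excreted ({excreta_total})"
        )
    return excreta_to_farmland / excreta_total


# ---------------------------------------------------------------------------
# environmental load series

#: load channel -> how fluxes are selected
_GAS_CHANNELS = {"NOx": "NOx", "NH3": "NH3", "N2O": "N2O"}


def environmental_load_series(network: Network, channel: str) -> pd.DataFrame:
    """Per-year, per-source totals of one pollution channel (Gg N y-1).

    ``channel`` is one of ``NOx``, ``NH3``, ``N2O`` (species-tagged fluxes into
    the atmosphere pool or across the boundary) or ``surface_water`` (all Nr
    discharged into the surface-water subsystem). Returns a year x source
    DataFrame; empty when no matching fluxes exist.
    """
    if channel in _GAS_CHANNELS:
        species = _GAS_CHANNELS[channel]
        records = [
            r
            for r in network
            if r.species == species
            and r.target in ("atmosphere", "surrounding_atmosphere")
        ]
    elif channel == "surface_water":
        records = [r for r in network if r.target == "surface_water"]
    else:
        raise DomainError(
            f"unknown load channel {channel!r}; expected NOx, NH3, N2O or surface_water"
        )
    if not records:
        return pd.DataFrame()
    frame = pd.DataFrame(
        [{"year": r.year, "source": r.source, "value": r.value} for r in records]
    )
    return frame.pivot_table(
        index="year", columns="source", values="value", aggfunc="sum", fill_value=0.0
    )


# ---------------------------------------------------------------------------
# life-cycle chain traces

#: default stage -> flux-label map for the industrial N chain
INDUSTRIAL_CHAIN: dict[str, tuple[str, ...]] = {
    "hbnf": ("hbnf",),
    "fossil_fuel_fixation": ("fossil_fuel_fixation",),
    "imported_goods": ("import_goods",),
    "fertilizer_supply": ("fertilizer",),
    "atmospheric_emission": ("nox_emissions",),
    "trade_output": ("net_domestic_trade", "export"),
}

#: default stage -> flux-label map for the food N chain
FOOD_CHAIN: dict[str, tuple[str, ...]] = {
    "production_inputs": ("abnf", "fertilizer"),
    "food_intake": ("import_food", "local_food"),
    "wastewater": ("wastewater",),
}

_CHAINS = {"industrial": INDUSTRIAL_CHAIN, "food": FOOD_CHAIN}


@dataclass(frozen=True)
class LifeCycleTrace:
    """Ordered stage fluxes of a commodity chain (Gg N y-1)."""

    chain: str
    year: int
    stages: tuple[tuple[str, float], ...]

    def stage(self, name: str) -> float:
        for stage, value in self.stages:
            if stage == name:
                return value
        raise KeyError(name)

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "value_GgN"])


def trace_life_cycle(
    network: Network,
    chain: str,
    year: int,
    config: Mapping[str, tuple[str, ...]] | None = None,
) -> LifeCycleTrace:
    """Sum labelled fluxes stage by stage along a commodity chain.

    ``config`` maps stage names to flux labels; defaults cover the industrial
    and food chains with the package's label vocabulary. A stage referencing
    a label absent from the network's ``year`` slice is a configuration error.
    """
    if config is None:
        try:
            config = _CHAINS[chain]
        except KeyError:
            raise DomainError(
                f"unknown chain {chain!r}; expected 'industrial' or 'food'"
            ) from None
    present = {r.label for r in network if r.year == year}
    stages = []
    for stage, labels in config.items():
        missing = [lab for lab in labels if lab not in present]
        if missing:
            raise ConfigurationError(
                f"chain {chain!r} stage {stage!r} references fluxes absent in "
                f"{year}: {missing}"
            )
        stages.append((stage, sum(network.labelled(lab, year) for lab in labels)))
    return LifeCycleTrace(chain=chain, year=year, stages=tuple(stages))
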