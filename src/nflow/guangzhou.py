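"""Guangzhou 1995/2015 worked-example fixture.

Encodes the published aggregate N fluxes for Guangzhou (area 7434 km2): the
boundary-crossing inputs and outputs, the seven accumulating subsystems, the
handful of internal fluxes the study reports in its text, and the reported
socioeconomic driver table. Every published number carries a citation string
retrievable via :func:`citation`; the remaining internal edges are synthetic
*balancing flows* (provenance ``"balancing"``) whose only role is to close
each subsystem's budget at the published accumulation — they carry no claim
about the real routing.

Known inconsistency kept on purpose: the published 1995 totals do not close
(142.5 - 99.2 = 43.3 Gg vs a printed accumulation of 44.7 Gg, presumably
rounding of aggregated sub-fluxes). The ledger reports 43.3; the printed
44.7 is stored as the annotated constant ``accumulation_total_1995``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .network import FluxRecord, Network

AREA_KM2 = 7434.0

_T1 = "reported city budget: key N flows table (means with 5th/95th bounds)"
_FIG_BALANCE = "reported city budget: temporal N balance figure and results text"
_FIG_FLOWS = "reported city budget: process-group flow diagram (1995/2015 values)"
_TEXT_FATE = "reported city budget: fate-analysis results text"
_T2 = "reported city budget: socioeconomic driver decomposition table"

#: name -> (value, units, citation) for published constants used in tests and
#: derived indicators. Percentile bounds are fixture constants only; the
#: pipeline never recomputes them (the underlying activity data are not
#: public).
PRINTED: dict[str, tuple[float, str, str]] = {
    "input_total_2015": (301.5, "Gg N y-1", _FIG_BALANCE),
    "output_total_2015": (245.0, "Gg N y-1", _FIG_BALANCE),
    "accumulation_total_2015": (56.5, "Gg N y-1", _FIG_BALANCE),
    "input_total_1995": (142.5, "Gg N y-1", _FIG_BALANCE),
    "output_total_1995": (99.2, "Gg N y-1", _FIG_BALANCE),
    "accumulation_total_1995": (
        44.7,
        "Gg N y-1",
        _FIG_BALANCE + " [does not close: 142.5 - 99.2 = 43.3; kept as printed]",
    ),
    "bnf_2015": (15.4, "Gg N y-1", _T1),
    "hbnf_2015": (85.2, "Gg N y-1", _T1),
    "hbnf_p5_2015": (75.6, "Gg N y-1", _T1),
    "hbnf_p95_2015": (95.3, "Gg N y-1", _T1),
    "fossil_fixation_2015": (89.0, "Gg N y-1", _T1),
    "fossil_fixation_p5_2015": (66.7, "Gg N y-1", _T1),
    "fossil_fixation_p95_2015": (113.0, "Gg N y-1", _T1),
    "import_2015": (111.9, "Gg N y-1", _T1),
    "n2_output_2015": (70.7, "Gg N y-1", _T1),
    "atmospheric_transfer_2015": (100.8, "Gg N y-1", _T1),
    "surface_water_transfer_2015": (22.8, "Gg N y-1", _T1),
    "net_domestic_trade_2015": (47.0, "Gg N y-1", _T1),
    "export_2015": (3.7, "Gg N y-1", _T1),
    "accumulation_farmland_2015": (11.3, "Gg N y-1", _T1),
    "accumulation_farmland_p5_2015": (2.1, "Gg N y-1", _T1),
    "accumulation_farmland_p95_2015": (22.5, "Gg N y-1", _T1),
    "accumulation_livestock_2015": (1.0, "Gg N y-1", _T1),
    "accumulation_forest_2015": (8.0, "Gg N y-1", _T1),
    "accumulation_aquaculture_2015": (1.9, "Gg N y-1", _T1),
    "accumulation_human_2015": (20.3, "Gg N y-1", _T1),
    "accumulation_urban_green_2015": (2.6, "Gg N y-1", _T1),
    "accumulation_ground_water_2015": (11.4, "Gg N y-1", _T1),
    "anthropogenic_creation_1995": (90.9, "Gg N y-1", _FIG_BALANCE),
    "anthropogenic_creation_2015": (180.0, "Gg N y-1", _FIG_BALANCE),
    "hbnf_1995": (56.8, "Gg N y-1", _TEXT_FATE),
    "fossil_fixation_1995": (26.0, "Gg N y-1", _FIG_BALANCE),
    "fertilizer_n_1995": (52.3, "Gg N y-1", _TEXT_FATE + " (92% of HBNF in 1995)"),
    "food_n_to_human_2015": (76.6, "Gg N y-1", _TEXT_FATE),
    "domestic_wastewater_to_surface_water_2015": (36.6, "Gg N y-1", _TEXT_FATE),
    "domestic_wastewater_to_surface_water_1995": (4.9, "Gg N y-1", _TEXT_FATE),
    "nox_emissions_1995": (34.2, "Gg N y-1", _TEXT_FATE),
    "nox_emissions_2015": (92.3, "Gg N y-1", _TEXT_FATE),
    "surface_water_input_1995": (17.2, "Gg N y-1", _TEXT_FATE),
    "surface_water_input_2015": (47.2, "Gg N y-1", _TEXT_FATE),
    "ocean_transfer_1995": (8.1, "Gg N y-1", _TEXT_FATE),
    "garbage_load_1995": (3.3, "Gg N y-1", _TEXT_FATE),
    "garbage_load_2015": (18.8, "Gg N y-1", _TEXT_FATE),
    "recycling_ratio_livestock_1995": (0.48, "fraction", _TEXT_FATE),
    "recycling_ratio_livestock_2015": (0.42, "fraction", _TEXT_FATE),
    "recycling_ratio_human_1995": (0.70, "fraction", _TEXT_FATE),
    "recycling_ratio_human_2015": (0.11, "fraction", _TEXT_FATE),
    "human_absorption_ratio_1995": (0.044, "fraction", _TEXT_FATE),
    "human_absorption_ratio_2015": (0.026, "fraction", _TEXT_FATE),
    "r_squared": (0.940, "1", _T2),
    "contribution_rate_population_printed": (34.10, "%", _T2 + " [inconsistent with its own formula; see module docs]"),
    "contribution_rate_diet_printed": (18.06, "%", _T2),
    "contribution_rate_energy_printed": (13.25, "%", _T2),
    "contribution_rate_industry_printed": (30.51, "%", _T2),
}


def printed(name: str) -> float:
    """Published value of a fixture constant."""
    return PRINTED[name][0]


def citation(name: str) -> str:
    """Citation string for a published fixture constant."""
    return PRINTED[name][2]


# ---------------------------------------------------------------------------
# flux tables
#
# Each tuple: (source, target, value, species, label, provenance)
# provenance "printed" = published magnitude; "balancing" = synthetic routing
# chosen so per-subsystem budgets close at the published accumulations.

_EDGES_2015 = (
    # boundary inputs
    ("fixation_source", "farmland", 5.8, "total_N", "abnf", "balancing"),
    ("fixation_source", "farmland", 9.6, "total_N", "nbnf", "balancing"),
    ("fixation_source", "industry", 85.2, "total_N", "hbnf", "printed"),
    ("fixation_source", "industry", 89.0, "NOx", "fossil_fuel_fixation", "printed"),
    ("world_trade", "human", 61.5, "product_N", "import_food", "balancing"),
    ("world_trade", "industry", 50.4, "product_N", "import_goods", "balancing"),
    # boundary outputs
    ("industry", "world_trade", 47.0, "product_N", "net_domestic_trade", "printed"),
    ("industry", "world_trade", 3.7, "product_N", "export", "printed"),
    ("surface_water", "ocean", 22.8, "NO3_NH4", "surface_water_transfer", "printed"),
    ("atmosphere", "surrounding_atmosphere", 70.7, "N2", "denitrified_n2", "printed"),
    ("atmosphere", "surrounding_atmosphere", 100.8, "total_N", "atmospheric_transfer", "printed"),
    # internal: industry
    ("industry", "farmland", 48.0, "product_N", "fertilizer", "balancing"),
    ("industry", "livestock", 3.9, "product_N", "feed_livestock", "balancing"),
    ("industry", "aquaculture", 2.7, "product_N", "feed_aquaculture", "balancing"),
    ("industry", "atmosphere", 92.3, "NOx", "nox_emissions", "printed"),
    ("industry", "atmosphere", 27.0, "total_N", "other_industrial_emissions", "balancing"),
    # internal: farmland
    ("farmland", "human", 15.1, "product_N", "local_food", "balancing"),
    ("farmland", "atmosphere", 21.9, "NH3", "farmland_emissions", "balancing"),
    ("farmland", "ground_water", 11.4, "NO3_NH4", "leaching", "balancing"),
    ("farmland", "surface_water", 3.7, "NO3_NH4", "runoff", "balancing"),
    # internal: livestock / aquaculture discharges
    ("livestock", "surface_water", 2.9, "organic_N", "livestock_discharge", "balancing"),
    ("aquaculture", "surface_water", 0.8, "organic_N", "aquaculture_discharge", "balancing"),
    # internal: human and treatment
    ("human", "sewage_disposal", 36.6, "organic_N", "wastewater", "printed"),
    ("human", "atmosphere", 19.7, "NH3", "human_emissions", "balancing"),
    ("human", "garbage_disposal", 18.8, "organic_N", "garbage", "printed"),
    ("garbage_disposal", "human", 18.8, "product_N", "recycled_garbage", "balancing"),
    ("sewage_disposal", "surface_water", 36.6, "NO3_NH4", "treated_effluent", "balancing"),
    # internal: environment media
    ("surface_water", "atmosphere", 24.4, "N2", "water_denitrification", "balancing"),
    ("atmosphere", "forest", 8.0, "NO3_NH4", "deposition_forest", "balancing"),
    ("atmosphere", "urban_green", 2.6, "NO3_NH4", "deposition_green", "balancing"),
    ("atmosphere", "surface_water", 3.2, "NO3_NH4", "deposition_water", "balancing"),
)

_EDGES_1995 = (
    # boundary inputs
    ("fixation_source", "farmland", 8.1, "total_N", "abnf", "printed"),
    ("fixation_source", "farmland", 9.6, "total_N", "nbnf", "balancing"),
    ("fixation_source", "industry", 56.8, "total_N", "hbnf", "printed"),
    ("fixation_source", "industry", 26.0, "NOx", "fossil_fuel_fixation", "printed"),
    ("world_trade", "human", 15.5, "product_N", "import_food", "balancing"),
    ("world_trade", "industry", 26.5, "product_N", "import_goods", "balancing"),
    # boundary outputs
    ("industry", "world_trade", 18.1, "product_N", "net_domestic_trade", "balancing"),
    ("industry", "world_trade", 3.0, "product_N", "export", "balancing"),
    ("surface_water", "ocean", 8.1, "NO3_NH4", "surface_water_transfer", "printed"),
    ("atmosphere", "surrounding_atmosphere", 30.0, "N2", "denitrified_n2", "balancing"),
    ("atmosphere", "surrounding_atmosphere", 40.0, "total_N", "atmospheric_transfer", "balancing"),
    # internal: industry
    ("industry", "farmland", 52.3, "product_N", "fertilizer", "printed"),
    ("industry", "livestock", 0.8, "product_N", "feed_livestock", "balancing"),
    ("industry", "aquaculture", 0.9, "product_N", "feed_aquaculture", "balancing"),
    ("industry", "atmosphere", 34.2, "NOx", "nox_emissions", "printed"),
    # internal: farmland
    ("farmland", "human", 10.0, "product_N", "local_food", "balancing"),
    ("farmland", "atmosphere", 24.7, "NH3", "farmland_emissions", "balancing"),
    ("farmland", "ground_water", 5.0, "NO3_NH4", "leaching", "balancing"),
    ("farmland", "surface_water", 12.3, "NO3_NH4", "runoff", "balancing"),
    # internal: human and treatment
    ("human", "sewage_disposal", 4.9, "organic_N", "wastewater", "printed"),
    ("human", "atmosphere", 7.6, "NH3", "human_emissions", "balancing"),
    ("human", "garbage_disposal", 3.3, "organic_N", "garbage", "printed"),
    ("garbage_disposal", "human", 3.3, "product_N", "recycled_garbage", "balancing"),
    ("sewage_disposal", "surface_water", 4.9, "NO3_NH4", "treated_effluent", "balancing"),
    # internal: environment media
    ("surface_water", "atmosphere", 9.1, "N2", "water_denitrification", "balancing"),
    ("atmosphere", "forest", 4.6, "NO3_NH4", "deposition_forest", "balancing"),
    ("atmosphere", "urban_green", 1.0, "NO3_NH4", "deposition_green", "balancing"),
)

#: label -> provenance ("printed" | "balancing") per year
PROVENANCE: dict[int, dict[str, str]] = {
    2015: {label: prov for *_x, label, prov in _EDGES_2015},
    1995: {label: prov for *_x, label, prov in _EDGES_1995},
}

_DRIVER_ROWS = (
    # factor, annual growth rate (%), elasticity, printed EC, stars
    ("population", 2.352, 0.957, 1.022, "***"),
    ("diet_choice", 0.456, 2.620, 1.012, "**"),
    ("energy_intensity", -3.527, 0.243, 0.991, "*"),
    ("industrial_level", 0.364, 5.617, 1.021, "***"),
)


@dataclass(frozen=True)
class GuangzhouFixture:
    """Published 1995/2015 networks plus the reported driver table."""

    networks: Mapping[int, Network]
    drivers: pd.DataFrame
    area_km2: float = AREA_KM2
    impact_growth_rate: float = 0.04904  # anthropogenic Nr creation, % y-1 / 100
    r_squared: float = 0.940

    @property
    def network_1995(self) -> Network:
        return self.networks[1995]

    @property
    def network_2015(self) -> Network:
        return self.networks[2015]

    def combined(self) -> Network:
        """Both years merged into one multi-year network."""
        return Network(tuple(self.network_1995) + tuple(self.network_2015))


def _build(year: int, edges) -> Network:
    return Network(
        FluxRecord(
            source=src,
            target=tgt,
            year=year,
            value=value,
            species=species,
            grade="moderate",
            label=label,
        )
        for src, tgt, value, species, label, _prov in edges
    )


def guangzhou_fixture() -> GuangzhouFixture:
    """Build the two published networks and the reported driver summary."""
    drivers = pd.DataFrame(
        _DRIVER_ROWS,
        columns=["factor", "growth_rate_pct", "coefficient", "printed_ec", "stars"],
    )
    return GuangzhouFixture(
        networks={1995: _build(1995, _EDGES_1995), 2015: _build(2015, _EDGES_2015)},
        drivers=drivers,
    )
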