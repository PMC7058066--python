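"""Synthetic city scenarios: the study conditions in generated form.

:func:`generate_city` builds a 21-year (1995-2015 by default) megalopolis
scenario with the statistical structure urban N budgets assume: activities
follow exponential trends times lognormal noise, with rising population,
energy use and imports, a slowly shrinking farmland base and a diet drifting
toward animal protein. Flux definitions map those activities through N
contents and emission factors onto the 12-subsystem network; per-compartment
accumulations absorb the input-output residuals, so every evaluated yearly
network satisfies the budget identity exactly by construction.

The generator is structural, not a reconstruction of any real city's
magnitudes: defaults are chosen so the headline fluxes land in the tens of
Gg N y-1 and the driver growth rates match those reported for a fast-growing
south-Chinese megacity (population +2.35 % y-1, animal-food share
+0.46 % y-1, energy intensity -3.5 % y-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .engine import FluxDefinition, FluxTerm, evaluate_scenario
from .errors import ConfigurationError
from .grades import ReliabilityGrade
from .network import Network
from .stirpat import StirpatDataset


@dataclass(frozen=True)
class Trend:
    """Exponential activity trend: level(t) = initial * (1+growth)^t * noise."""

    initial: float
    growth: float
    unit: str
    subsystem: str
    grade: str = "moderate"

    def __post_init__(self):
        if self.initial < 0:
            raise ConfigurationError(f"initial level must be nonnegative, got {self.initial}")
        if self.growth <= -1:
            raise ConfigurationError(f"growth rate must exceed -1, got {self.growth}")


def _default_trends() -> dict[str, Trend]:
    return {
        # people and economy
        "population": Trend(8.48e6, 0.02352, "capita", "human", "high"),
        "gdp": Trend(1250.0, 0.094, "1", "industry", "high"),
        "animal_food_share": Trend(0.294, 0.00456, "1", "human", "moderate"),
        # energy
        "coal_consumption": Trend(20.0, 0.040, "Mt", "industry", "high"),
        "oil_consumption": Trend(6.0, 0.080, "Mt", "industry", "high"),
        # industry and trade
        "synthetic_ammonia_n": Trend(55.0, 0.021, "kt", "industry", "moderate"),
        "food_import": Trend(900.0, 0.055, "kt", "human", "moderate"),
        "goods_import": Trend(400.0, 0.070, "kt", "industry", "low"),
        # agriculture (declining)
        "chemical_fertilizer": Trend(170.0, -0.001, "kt", "farmland", "high"),
        "crop_harvest": Trend(600.0, -0.010, "kt", "farmland", "moderate"),
        "farmland_area": Trend(1.6e5, -0.012, "ha", "farmland", "high"),
        "forest_area": Trend(2.8e5, 0.001, "ha", "forest", "high"),
        "livestock_heads": Trend(3.0e6, -0.010, "head", "livestock", "moderate"),
        "straw_burned": Trend(150.0, -0.020, "kt", "farmland", "low"),
        "aquaculture_production": Trend(40.0, 0.020, "kt", "aquaculture", "moderate"),
        "urban_green_area": Trend(2.0e4, 0.020, "ha", "urban_green", "high"),
    }


_DEFAULT_PARAMETERS: tuple[tuple[str, float, str, str], ...] = (
    # name, value, unit, grade
    ("n_unity", 1.0, "1", "moderate"),
    ("ef_n_coal", 0.9, "kg/t", "high"),
    ("ef_n_oil", 1.3, "kg/t", "high"),
    ("abnf_rate", 50.0, "kg/ha", "moderate"),
    ("nbnf_rate", 35.0, "kg/ha", "low"),
    ("n_content_food", 30.0, "kg/t", "moderate"),
    ("n_content_goods", 25.0, "kg/t", "low"),
    ("n_content_fertilizer", 300.0, "kg/t", "high"),
    ("n_content_grain", 20.0, "kg/t", "moderate"),
    ("ef_nox_coal", 0.85, "kg/t", "moderate"),
    ("ef_nox_oil", 1.2, "kg/t", "moderate"),
    ("ef_nox_straw", 8.0, "kg/t", "low"),
    ("ef_nh3_fertilizer", 90.0, "kg/t", "moderate"),
    ("ef_nh3_human", 0.3, "kg/capita", "moderate"),
    ("ef_runoff_fertilizer", 20.0, "kg/t", "moderate"),
    ("ef_leach_fertilizer", 25.0, "kg/t", "low"),
    ("feed_rate_livestock", 2.0, "kg/head", "moderate"),
    ("excreta_return_rate", 0.9, "kg/head", "low"),
    ("wastewater_rate", 2.0, "kg/capita", "high"),
    ("effluent_rate", 1.2, "kg/capita", "moderate"),
    ("ef_n2o_sewage", 0.05, "kg/capita", "low"),
    ("denit_rate_sewage", 0.8, "kg/capita", "low"),
    ("denit_rate_fertilizer", 30.0, "kg/t", "low"),
    ("feed_rate_aquaculture", 25.0, "kg/t", "moderate"),
    ("n_content_aquafood", 20.0, "kg/t", "moderate"),
    ("green_fertilizer_rate", 30.0, "kg/ha", "moderate"),
    ("ef_nh3_green", 5.0, "kg/ha", "low"),
    ("garbage_rate", 1.5, "kg/capita", "moderate"),
    ("ef_nh3_garbage", 0.2, "kg/capita", "low"),
)


def _default_definitions() -> tuple[FluxDefinition, ...]:
    d = FluxDefinition
    t = FluxTerm
    return (
        # new-Nr creation
        d("abnf", "fixation_source", "farmland", "total_N",
          (t("farmland_area", "abnf_rate"),)),
        d("nbnf", "fixation_source", "forest", "total_N",
          (t("forest_area", "nbnf_rate"),)),
        d("hbnf", "fixation_source", "industry", "total_N",
          (t("synthetic_ammonia_n", "n_unity"),)),
        d("fossil_fuel_fixation", "fixation_source", "industry", "NOx",
          (t("coal_consumption", "ef_n_coal"), t("oil_consumption", "ef_n_oil"))),
        # trade
        d("import_food", "world_trade", "human", "product_N",
          (t("food_import", "n_content_food"),)),
        d("import_goods", "world_trade", "industry", "product_N",
          (t("goods_import", "n_content_goods"),)),
        d("export", "industry", "world_trade", "product_N",
          (t("synthetic_ammonia_n", "n_unity", 0.08),)),
        d("net_domestic_trade", "industry", "world_trade", "product_N",
          (t("goods_import", "n_content_goods", 0.3),
           t("synthetic_ammonia_n", "n_unity", 0.12),)),
        # agricultural chain
        d("fertilizer", "industry", "farmland", "product_N",
          (t("chemical_fertilizer", "n_content_fertilizer"),)),
        d("feed_livestock", "industry", "livestock", "product_N",
          (t("livestock_heads", "feed_rate_livestock"),)),
        d("feed_aquaculture", "industry", "aquaculture", "product_N",
          (t("aquaculture_production", "feed_rate_aquaculture"),)),
        d("green_fertilizer", "industry", "urban_green", "product_N",
          (t("urban_green_area", "green_fertilizer_rate"),)),
        d("industrial_products", "industry", "human", "product_N",
          (t("synthetic_ammonia_n", "n_unity", 0.25),
           t("goods_import", "n_content_goods", 0.4))),
        d("local_food", "farmland", "human", "product_N",
          (t("crop_harvest", "n_content_grain"),)),
        d("aqua_food", "aquaculture", "human", "product_N",
          (t("aquaculture_production", "n_content_aquafood"),)),
        d("excreta_return", "livestock", "farmland", "organic_N",
          (t("livestock_heads", "excreta_return_rate"),)),
        # atmospheric emissions
        d("nox_emissions", "industry", "atmosphere", "NOx",
          (t("coal_consumption", "ef_nox_coal"), t("oil_consumption", "ef_nox_oil"))),
        d("straw_nox", "farmland", "atmosphere", "NOx",
          (t("straw_burned", "ef_nox_straw"),)),
        d("nh3_fertilizer", "farmland", "atmosphere", "NH3",
          (t("chemical_fertilizer", "ef_nh3_fertilizer"),)),
        d("nh3_human", "human", "atmosphere", "NH3",
          (t("population", "ef_nh3_human"),)),
        d("sewage_n2o", "sewage_disposal", "atmosphere", "N2O",
          (t("population", "ef_n2o_sewage"),)),
        d("green_nh3", "urban_green", "atmosphere", "NH3",
          (t("urban_green_area", "ef_nh3_green"),)),
        d("garbage", "human", "garbage_disposal", "organic_N",
          (t("population", "garbage_rate"),)),
        d("garbage_nh3", "garbage_disposal", "atmosphere", "NH3",
          (t("population", "ef_nh3_garbage"),)),
        # water pathway
        d("runoff", "farmland", "surface_water", "NO3_NH4",
          (t("chemical_fertilizer", "ef_runoff_fertilizer"),)),
        d("leaching", "farmland", "ground_water", "NO3_NH4",
          (t("chemical_fertilizer", "ef_leach_fertilizer"),)),
        d("wastewater", "human", "sewage_disposal", "organic_N",
          (t("population", "wastewater_rate"),)),
        d("treated_effluent", "sewage_disposal", "surface_water", "NO3_NH4",
          (t("population", "effluent_rate"),)),
        d("surface_water_transfer", "surface_water", "ocean", "NO3_NH4",
          (t("population", "effluent_rate", 0.5),
           t("chemical_fertilizer", "ef_runoff_fertilizer", 0.5))),
        # terminal sinks
        d("sewage_denitrification", "sewage_disposal", "surrounding_atmosphere", "N2",
          (t("population", "denit_rate_sewage"),)),
        d("farmland_denitrification", "farmland", "surrounding_atmosphere", "N2",
          (t("chemical_fertilizer", "denit_rate_fertilizer"),)),
        d("atmospheric_transfer", "atmosphere", "surrounding_atmosphere", "NOx",
          (t("coal_consumption", "ef_nox_coal", 0.9),
           t("oil_consumption", "ef_nox_oil", 0.9),
           t("chemical_fertilizer", "ef_nh3_fertilizer", 0.65),
           t("population", "ef_nh3_human", 0.65))),
        d("deposition_forest", "atmosphere", "forest", "NO3_NH4",
          (t("chemical_fertilizer", "ef_nh3_fertilizer", 0.25),)),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the synthetic city generator."""

    start_year: int = 1995
    n_years: int = 21
    seed: int = 0
    noise_cv: float = 0.03
    area_km2: float = 7400.0
    name: str = "synthetic-city"
    trends: Mapping[str, Trend] = field(default_factory=_default_trends)

    def __post_init__(self):
        if self.n_years < 1:
            raise ConfigurationError("n_years must be >= 1")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")


@dataclass(frozen=True, eq=False)
class CityScenario:
    """Everything the pipeline needs for one city: activity and parameter
    tables, flux definitions, driver series, area and metadata."""

    name: str
    area_km2: float
    seed: int
    activities: pd.DataFrame        # year, subsystem, item, amount, unit, grade
    parameters: pd.DataFrame        # name, value, unit, grade
    definitions: tuple[FluxDefinition, ...]
    drivers: pd.DataFrame | None = None   # year, I_GgN, population, ...

    # -- lookups ------------------------------------------------------------
    def activity_amount(self, year: int, item: str) -> float:
        rows = self.activities[
            (self.activities["year"] == year) & (self.activities["item"] == item)
        ]
        if rows.empty:
            raise ConfigurationError(f"no activity {item!r} in year {year}")
        return float(rows["amount"].iloc[0])

    def parameter_value(self, name: str) -> float:
        rows = self.parameters[self.parameters["name"] == name]
        if rows.empty:
            raise ConfigurationError(f"no parameter {name!r}")
        return float(rows["value"].iloc[0])

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.activities["year"].unique().tolist()))

    # -- Monte Carlo support -------------------------------------------------
    def with_multipliers(self, activity_mult, parameter_mult) -> "CityScenario":
        """Copy with each activity amount / parameter value scaled row-wise."""
        acts = self.activities.assign(amount=self.activities["amount"].to_numpy() * activity_mult)
        pars = self.parameters.assign(value=self.parameters["value"].to_numpy() * parameter_mult)
        return replace(self, activities=acts, parameters=pars)

    # -- evaluation ----------------------------------------------------------
    def evaluate(self) -> Network:
        return Network(evaluate_scenario(self))

    def stirpat_dataset(self) -> StirpatDataset:
        if self.drivers is None:
            raise ConfigurationError("scenario carries no driver series")
        return StirpatDataset.from_frame(self.drivers)

    def equals(self, other: "CityScenario") -> bool:
        """Content equality up to row ordering of the tables."""

        def canon(frame: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
            return frame.sort_values(keys, kind="stable").reset_index(drop=True)

        if (self.name, self.area_km2, self.seed) != (other.name, other.area_km2, other.seed):
            return False
        if self.definitions != other.definitions:
            return False
        if not canon(self.activities, ["year", "item"]).equals(
            canon(other.activities, ["year", "item"])
        ):
            return False
        if not canon(self.parameters, ["name"]).equals(canon(other.parameters, ["name"])):
            return False
        if (self.drivers is None) != (other.drivers is None):
            return False
        if self.drivers is not None and not canon(self.drivers, ["year"]).equals(
            canon(other.drivers, ["year"])
        ):
            return False
        return True


def generate_city(config: ScenarioConfig = ScenarioConfig()) -> CityScenario:
    """Generate a deterministic synthetic city scenario from ``config``.

    Trend components are deterministic; lognormal noise (sigma = noise_cv)
    depends only on the seed, so distinct seeds share trends but differ in
    noise. Driver series (impact, population, diet, energy intensity,
    industrial level) are derived from the evaluated fluxes.
    """
    rng = np.random.default_rng(config.seed)
    years = np.arange(config.start_year, config.start_year + config.n_years)
    rows = []
    for item in sorted(config.trends):
        trend = config.trends[item]
        levels = trend.initial * (1.0 + trend.growth) ** np.arange(config.n_years)
        if config.noise_cv > 0:
            noise = rng.lognormal(mean=0.0, sigma=config.noise_cv, size=config.n_years)
        else:
            noise = np.ones(config.n_years)
        for year, level in zip(years, levels * noise):
            rows.append(
                {
                    "year": int(year),
                    "subsystem": trend.subsystem,
                    "item": item,
                    "amount": float(level),
                    "unit": trend.unit,
                    "grade": trend.grade,
                }
            )
    activities = pd.DataFrame(rows, columns=["year", "subsystem", "item", "amount", "unit", "grade"])
    parameters = pd.DataFrame(
        _DEFAULT_PARAMETERS, columns=["name", "value", "unit", "grade"]
    )
    scenario = CityScenario(
        name=config.name,
        area_km2=config.area_km2,
        seed=config.seed,
        activities=activities,
        parameters=parameters,
        definitions=_default_definitions(),
    )
    try:
        drivers = _derive_drivers(scenario)
    except (ConfigurationError, ZeroDivisionError):
        # a reduced trend set cannot support the driver series; leave them out
        drivers = None
    return replace(scenario, drivers=drivers)


def _derive_drivers(scenario: CityScenario) -> pd.DataFrame:
    """Socioeconomic driver series from the evaluated flux network."""
    network = scenario.evaluate()
    rows = []
    for year in scenario.years:
        hbnf = network.labelled("hbnf", year)
        fossil = network.labelled("fossil_fuel_fixation", year)
        abnf = network.labelled("abnf", year)
        nbnf = network.labelled("nbnf", year)
        creation = hbnf + fossil + abnf + nbnf
        energy = scenario.activity_amount(year, "coal_consumption") + scenario.activity_amount(
            year, "oil_consumption"
        )
        rows.append(
            {
                "year": year,
                "I_GgN": hbnf + fossil + abnf,  # anthropogenic creation
                "population": scenario.activity_amount(year, "population"),
                "diet_choice": scenario.activity_amount(year, "animal_food_share"),
                "energy_intensity": energy / scenario.activity_amount(year, "gdp"),
                "industrial_level": hbnf / creation,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# STIRPAT simulation (construction oracle for recovery studies)


def simulate_stirpat_dataset(
    coefficients: Mapping[str, float],
    growth_rates: Mapping[str, float] | None = None,
    n_years: int = 21,
    predictor_noise_sd: float = 0.10,
    response_noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 0.0,
) -> StirpatDataset:
    """Simulate driver series from the ln-linear model itself.

    Predictors follow exponential trends (default growth rates as reported
    for a fast-growing megacity) perturbed by lognormal noise so they are not
    collinear in time; the impact is computed exactly from the model (plus
    optional Gaussian noise on ln I). With ``response_noise_sd=0`` an OLS fit
    must recover the coefficients to machine precision.

    ``coefficients`` maps factor names (population, diet_choice,
    energy_intensity, industrial_level) to elasticities.
    """
    from .stirpat import FACTORS  # local import to avoid cycle at module load

    if growth_rates is None:
        growth_rates = {
            "population": 0.02352,
            "diet_choice": 0.00456,
            "energy_intensity": -0.03527,
            "industrial_level": 0.00364,
        }
    initials = {
        "population": 8.48e6,
        "diet_choice": 0.294,
        "energy_intensity": 2.5,
        "industrial_level": 0.40,
    }
    rng = np.random.default_rng(seed)
    t = np.arange(n_years)
    series = {}
    for factor in FACTORS:
        trend = initials[factor] * (1.0 + growth_rates[factor]) ** t
        noise = rng.lognormal(0.0, predictor_noise_sd, n_years)
        series[factor] = trend * noise
    ln_i = intercept + sum(
        coefficients[f] * np.log(series[f]) for f in FACTORS
    )
    if response_noise_sd > 0:
        ln_i = ln_i + rng.normal(0.0, response_noise_sd, n_years)
    return StirpatDataset(
        years=tuple(range(1995, 1995 + n_years)),
        impact=tuple(np.exp(ln_i)),
        population=tuple(series["population"]),
        diet_choice=tuple(series["diet_choice"]),
        energy_intensity=tuple(series["energy_intensity"]),
        industrial_level=tuple(series["industrial_level"]),
    )


# ---------------------------------------------------------------------------
# serialization

_ACTIVITY_COLS = ["year", "subsystem", "item", "amount", "unit", "grade"]
_PARAMETER_COLS = ["name", "value", "unit", "grade"]


def write_scenario(scenario: CityScenario, path: str | Path) -> None:
    """Write a scenario directory: activities.csv, parameters.csv,
    flux_defs.yaml, drivers.csv, meta.yaml (canonical forms; a write-read-
    write cycle is byte identical)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    acts = scenario.activities[_ACTIVITY_COLS].sort_values(["year", "item"], kind="stable")
    acts.to_csv(path / "activities.csv", index=False)
    scenario.parameters[_PARAMETER_COLS].to_csv(path / "parameters.csv", index=False)
    defs = [
        {
            "label": d.label,
            "source": d.source,
            "target": d.target,
            "species": d.species,
            "terms": [
                {
                    "activity": term.activity,
                    "parameter": term.parameter,
                    "multiplier": term.multiplier,
                }
                for term in d.terms
            ],
        }
        for d in scenario.definitions
    ]
    (path / "flux_defs.yaml").write_text(yaml.safe_dump(defs, sort_keys=False))
    if scenario.drivers is not None:
        scenario.drivers.to_csv(path / "drivers.csv", index=False)
    meta = {"name": scenario.name, "area_km2": scenario.area_km2, "seed": scenario.seed}
    (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_definitions(path: str | Path) -> tuple[FluxDefinition, ...]:
    """Parse a flux_defs.yaml file into definitions."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"malformed flux definition file {path}: {exc}") from exc
    defs = []
    for i, entry in enumerate(raw or []):
        try:
            defs.append(
                FluxDefinition(
                    label=entry["label"],
                    source=entry["source"],
                    target=entry["target"],
                    species=entry.get("species", "total_N"),
                    terms=tuple(
                        FluxTerm(
                            activity=t["activity"],
                            parameter=t["parameter"],
                            multiplier=float(t.get("multiplier", 1.0)),
                        )
                        for t in entry.get("terms", [])
                    ),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(
                f"malformed flux definition entry {i} in {path}: {exc}"
            ) from exc
    return tuple(defs)


def read_scenario(path: str | Path) -> CityScenario:
    """Read a scenario directory written by :func:`write_scenario`."""
    path = Path(path)
    try:
        activities = pd.read_csv(path / "activities.csv", float_precision="round_trip")
        parameters = pd.read_csv(path / "parameters.csv", float_precision="round_trip")
        meta = yaml.safe_load((path / "meta.yaml").read_text())
    except FileNotFoundError as exc:
        raise ConfigurationError(f"incomplete scenario directory {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"malformed meta.yaml in {path}: {exc}") from exc
    from .compartments import REGISTRY

    bad = set(activities["subsystem"]) - set(REGISTRY)
    if bad:
        first = activities[activities["subsystem"].isin(bad)].index[0]
        raise ConfigurationError(
            f"activities.csv line {first + 2}: unknown subsystem id(s) {sorted(bad)}"
        )
    drivers_path = path / "drivers.csv"
    drivers = (
        pd.read_csv(drivers_path, float_precision="round_trip")
        if drivers_path.exists()
        else None
    )
    return CityScenario(
        name=meta["name"],
        area_km2=float(meta["area_km2"]),
        seed=int(meta["seed"]),
        activities=activities,
        parameters=parameters,
        definitions=read_definitions(path / "flux_defs.yaml"),
        drivers=drivers,
    )
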