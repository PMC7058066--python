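"""Shared fixtures: the published worked example, a synthetic city, and a
random-network factory used by the conservation/oracle tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nflow import (
    CityScenario,
    FluxRecord,
    Network,
    ScenarioConfig,
    generate_city,
    guangzhou_fixture,
)
from nflow.compartments import EXTERNAL, SUBSYSTEMS

ALL_IDS = SUBSYSTEMS + EXTERNAL


@pytest.fixture(scope="session")
def gz():
    return guangzhou_fixture()


@pytest.fixture(scope="session")
def city():
    return generate_city(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def city_network(city):
    return city.evaluate()


def make_random_network(rng: np.random.Generator, n_fluxes: int = 6) -> Network:
    """Random small network over the full compartment registry."""
    records = []
    for i in range(n_fluxes):
        src, tgt = rng.choice(len(ALL_IDS), size=2, replace=False)
        records.append(
            FluxRecord(
                source=ALL_IDS[src],
                target=ALL_IDS[tgt],
                year=int(rng.integers(2000, 2003)),
                value=float(rng.uniform(0.0, 50.0)),
                species=str(rng.choice(["total_N", "NOx", "NH3", "N2", "NO3_NH4"])),
                grade="moderate",
                label=f"flux_{i}",
            )
        )
    return Network(records)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def single_parameter_scenario(mean: float = 100.0, grade: str = "high") -> CityScenario:
    """Minimal scenario with one graded parameter, for Monte Carlo checks."""
    return CityScenario(
        name="single-parameter",
        area_km2=1.0,
        seed=0,
        activities=pd.DataFrame(
            columns=["year", "subsystem", "item", "amount", "unit", "grade"]
        ),
        parameters=pd.DataFrame(
            [{"name": "x", "value": mean, "unit": "1", "grade": grade}]
        ),
        definitions=(),
    )
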