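"""Fate indicators: shares, fate fractions, NUE, recycling, load series, traces."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nflow import (
    ConfigurationError,
    ConsistencyError,
    DomainError,
    FluxRecord,
    Network,
    creation_partition,
    environment_share_of_outputs,
    environmental_load_series,
    fate_fractions,
    nue,
    recycling_ratio,
    share_of,
    trace_life_cycle,
)
from nflow.fate import round_half_away

from conftest import make_random_network


class TestShareOf:
    @pytest.mark.parametrize(
        ("part", "whole", "decimals", "expected"),
        [
            (111.9, 301.5, 1, 37.1),   # import share of total input
            (89.0, 301.5, 1, 29.5),    # fossil-fuel fixation share
            (85.2, 301.5, 1, 28.3),    # HBNF share
            (52.3, 56.8, 0, 92),       # fertilizer share of HBNF, 1995
            (0.0, 10.0, 1, 0.0),
        ],
    )
    def test_published_shares(self, part, whole, decimals, expected):
        assert share_of(part, whole, decimals) == expected

    def test_nonpositive_whole_rejected(self):
        with pytest.raises(DomainError):
            share_of(1.0, 0.0)

    @given(
        part=st.floats(min_value=0.0, max_value=100.0),
        whole=st.floats(min_value=0.5, max_value=100.0),
        k=st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_scale_invariance(self, part, whole, k):
        assert share_of(part, whole) == share_of(k * part, k * whole)

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(2.25, 1) == 2.3
        assert round_half_away(-2.25, 1) == -2.3
        assert round_half_away(92.07, 0) == 92.0


class TestFateFractions:
    def test_all_input_denitrified_toy_network(self):
        net = Network(
            [
                FluxRecord("fixation_source", "farmland", 2015, 10.0, label="bnf"),
                FluxRecord("farmland", "surrounding_atmosphere", 2015, 10.0,
                           species="N2", label="denit"),
            ]
        )
        ff = fate_fractions(net, 2015)
        assert ff.denitrified_n2 == 100.0
        assert ff.atmospheric_transfer == ff.surface_water_transfer == 0.0
        assert ff.trade_output == ff.terrestrial_accumulation == 0.0

    def test_worked_example_fractions(self, gz):
        ff = fate_fractions(gz.network_2015, 2015)
        assert ff.denitrified_n2 == 23.4
        assert ff.trade_output == 16.8
        assert ff.terrestrial_accumulation == 18.7
        assert ff.atmospheric_transfer == 33.4

    def test_components_close_to_hundred(self, gz):
        ff = fate_fractions(gz.network_2015, 2015)
        assert sum(ff.as_dict().values()) == pytest.approx(100.0, abs=0.2)

    def test_surface_water_raw_value_is_a_rounding_artifact(self, gz):
        # 22.8 / 301.5 = 7.56%; published as 7.7% through upstream rounding
        ff = fate_fractions(gz.network_2015, 2015)
        assert ff.raw["surface_water_transfer"] == pytest.approx(7.5622, abs=1e-3)
        assert ff.surface_water_transfer == 7.6

    def test_accepts_ledger_with_backref(self, gz):
        ledger = gz.network_2015.ledger()
        assert fate_fractions(ledger, 2015) == fate_fractions(gz.network_2015, 2015)

    def test_zero_input_year_is_domain_error(self, gz):
        with pytest.raises(DomainError):
            fate_fractions(gz.network_2015, 1887)

    def test_environment_share_of_outputs(self, gz):
        assert environment_share_of_outputs(gz.network_2015, 2015) == 50.4


class TestCreationPartition:
    def test_worked_example_partition(self, gz):
        cp = creation_partition(gz.network_2015, 2015)
        assert cp.bnf == pytest.approx(15.4)
        assert cp.hbnf == 85.2
        assert cp.fossil_fixation == 89.0
        assert cp.total_creation == pytest.approx(189.6)
        # anthropogenic creation excludes natural BNF only
        assert cp.anthropogenic_total == pytest.approx(180.0)
        # 180.0/189.6 = 94.94%; published as 95.0% through upstream rounding
        assert 100 * cp.anthropogenic_total / cp.total_creation == pytest.approx(
            94.94, abs=0.05
        )

    def test_1995_partition(self, gz):
        cp = creation_partition(gz.network_1995, 1995)
        assert cp.anthropogenic_total == pytest.approx(90.9)


class TestEfficiencyRatios:
    def test_nue_definition_and_oracle(self, rng):
        assert nue(0.0, 10.0) == 0.0
        assert nue(5.0, 10.0) == 0.5
        for _ in range(20):
            harvest, inputs = rng.uniform(0, 50), rng.uniform(1, 100)
            if harvest > inputs:
                harvest = inputs * 0.9
            assert nue(harvest, inputs) == pytest.approx(harvest / inputs)

    def test_nue_above_one_warns_of_soil_mining(self):
        with pytest.warns(UserWarning, match="soil mining"):
            assert nue(12.0, 10.0) == pytest.approx(1.2)

    def test_nue_requires_positive_inputs(self):
        with pytest.raises(DomainError):
            nue(1.0, 0.0)

    @pytest.mark.parametrize(
        ("returned", "total", "expected"),
        [(10.0, 10.0, 1.0), (0.0, 10.0, 0.0), (4.2, 10.0, 0.42)],
    )
    def test_recycling_ratio(self, returned, total, expected):
        assert recycling_ratio(returned, total) == pytest.approx(expected)

    def test_recycling_ratio_errors(self):
        with pytest.raises(DomainError):
            recycling_ratio(1.0, 0.0)
        with pytest.raises(ConsistencyError):
            recycling_ratio(11.0, 10.0)


class TestEnvironmentalLoad:
    def test_published_nox_series_endpoints(self, gz):
        series = environmental_load_series(gz.combined(), "NOx")
        totals = series.sum(axis=1)
        assert totals.loc[1995] == pytest.approx(34.2)
        assert totals.loc[2015] == pytest.approx(92.3)

    def test_no_matching_species_gives_empty_series(self, gz):
        net = Network([FluxRecord("farmland", "human", 2015, 1.0, label="food")])
        assert environmental_load_series(net, "N2O").empty

    def test_unknown_channel_rejected(self, gz):
        with pytest.raises(DomainError):
            environmental_load_series(gz.network_2015, "CH4")

    def test_agrees_with_filter_and_sum_oracle(self, rng):
        for _ in range(20):
            net = make_random_network(rng, n_fluxes=10)
            series = environmental_load_series(net, "NOx")
            oracle = sum(
                r.value
                for r in net
                if r.species == "NOx"
                and r.target in ("atmosphere", "surrounding_atmosphere")
            )
            got = float(series.to_numpy().sum()) if not series.empty else 0.0
            assert got == pytest.approx(oracle)

    def test_surface_water_channel_counts_all_discharges(self, gz):
        series = environmental_load_series(gz.combined(), "surface_water")
        assert series.sum(axis=1).loc[1995] == pytest.approx(17.2)
        assert series.sum(axis=1).loc[2015] == pytest.approx(47.2)


class TestLifeCycleTrace:
    def test_industrial_chain_hbnf_stage(self, gz):
        trace = trace_life_cycle(gz.network_2015, "industrial", 2015)
        assert trace.stage("hbnf") == 85.2
        assert trace.stage("fossil_fuel_fixation") == 89.0

    def test_food_chain_intake_matches_published_value(self, gz):
        trace = trace_life_cycle(gz.network_2015, "food", 2015)
        assert trace.stage("food_intake") == pytest.approx(76.6)

    def test_single_stage_toy_chain(self, gz):
        config = {"fertilizer_only": ("fertilizer",)}
        trace = trace_life_cycle(gz.network_1995, "industrial", 1995, config=config)
        assert trace.stages == (("fertilizer_only", 52.3),)

    def test_missing_label_is_configuration_error(self, gz):
        with pytest.raises(ConfigurationError, match="no_such_flux"):
            trace_life_cycle(
                gz.network_2015, "industrial", 2015,
                config={"stage": ("no_such_flux",)},
            )

    def test_unknown_chain_rejected(self, gz):
        with pytest.raises(DomainError):
            trace_life_cycle(gz.network_2015, "textile", 2015)

    def test_stage_outflows_bounded_by_inflows_plus_release(self, gz):
        # conservation sanity on the fixture's industrial chain: outputs of the
        # industry subsystem cannot exceed its inputs plus stock release
        b = gz.network_2015.balance("industry", 2015)
        assert b.outputs <= b.inputs + max(0.0, -b.accumulation) + 1e-9
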