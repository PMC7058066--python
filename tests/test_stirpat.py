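"""STIRPAT driver decomposition: growth rates, OLS fit, ECs, contributions."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nflow import (
    DomainError,
    SingularityError,
    StirpatDataset,
    annual_growth_rate,
    contribution_rates,
    decompose_drivers,
    effect_coefficient,
    fit_stirpat,
    screen_factors,
    simulate_stirpat_dataset,
)

#: published elasticities used as ground truth in recovery studies
TRUE_COEFS = {
    "population": 0.957,
    "diet_choice": 2.620,
    "energy_intensity": 0.243,
    "industrial_level": 5.617,
}


class TestAnnualGrowthRate:
    def test_constant_series_has_zero_growth(self):
        assert annual_growth_rate([5.0] * 10) == pytest.approx(0.0)

    def test_doubling_in_one_step_is_hundred_percent(self):
        assert annual_growth_rate([100.0, 200.0]) == pytest.approx(1.0)

    def test_recovers_constructed_exponential_rate(self):
        rate = 0.02352
        series = 100.0 * (1 + rate) ** np.arange(21)
        assert annual_growth_rate(series) == pytest.approx(rate, abs=1e-12)

    def test_nonpositive_endpoints_rejected(self):
        with pytest.raises(DomainError):
            annual_growth_rate([0.0, 1.0])


class TestFit:
    def test_noiseless_recovery_to_machine_precision(self):
        ds = simulate_stirpat_dataset(TRUE_COEFS, seed=0, intercept=1.5)
        fit = fit_stirpat(ds)
        for factor, true in TRUE_COEFS.items():
            assert fit.coefficients[factor] == pytest.approx(true, abs=1e-6)
        assert fit.intercept == pytest.approx(1.5, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_response_equal_to_one_predictor(self):
        ds = simulate_stirpat_dataset(
            {"population": 1.0, "diet_choice": 0.0,
             "energy_intensity": 0.0, "industrial_level": 0.0},
            seed=3,
        )
        fit = fit_stirpat(ds)
        assert fit.coefficients["population"] == pytest.approx(1.0, abs=1e-9)
        assert fit.coefficients["diet_choice"] == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_duplicated_predictor_is_singular_and_named(self):
        ds = simulate_stirpat_dataset(TRUE_COEFS, seed=0)
        clone = StirpatDataset(
            years=ds.years,
            impact=ds.impact,
            population=ds.population,
            diet_choice=ds.population,  # exact duplicate
            energy_intensity=ds.energy_intensity,
            industrial_level=ds.industrial_level,
        )
        with pytest.raises(SingularityError, match="population"):
            fit_stirpat(clone)

    def test_stars_follow_p_value_thresholds(self):
        ds = simulate_stirpat_dataset(
            TRUE_COEFS, n_years=100, response_noise_sd=0.05, seed=0
        )
        fit = fit_stirpat(ds)
        for factor in TRUE_COEFS:
            p, stars = fit.p_values[factor], fit.stars[factor]
            if p < 0.001:
                assert stars == "***"
            elif p < 0.01:
                assert stars == "**"
            elif p < 0.05:
                assert stars == "*"
            else:
                assert stars == ""

    def test_too_few_years_rejected(self):
        with pytest.raises(DomainError):
            simulate_stirpat_dataset(TRUE_COEFS, n_years=5, seed=0)

    def test_bias_vanishes_with_sample_size(self):
        errs = {}
        for n in (20, 1000):
            ds = simulate_stirpat_dataset(
                TRUE_COEFS, n_years=n, response_noise_sd=0.1, seed=12
            )
            fit = fit_stirpat(ds)
            errs[n] = max(
                abs(fit.coefficients[f] - TRUE_COEFS[f]) for f in TRUE_COEFS
            )
        assert errs[1000] < errs[20]
        assert errs[1000] < 0.05


class TestEffectCoefficient:
    @pytest.mark.parametrize(
        ("r", "b", "expected"),
        [
            (0.02352, 0.957, 1.022),   # population
            (0.00456, 2.620, 1.012),   # diet choice
            (-0.03527, 0.243, 0.991),  # energy intensity
            (0.00364, 5.617, 1.021),   # industrial level
            (0.37, 0.0, 1.0),
        ],
    )
    def test_published_effect_coefficients(self, r, b, expected):
        assert round(effect_coefficient(r, b), 3) == expected

    def test_nonpositive_base_rejected(self):
        with pytest.raises(DomainError):
            effect_coefficient(-1.5, 1.0)

    @given(
        r_mag=st.floats(min_value=1e-4, max_value=0.5),
        b_mag=st.floats(min_value=1e-4, max_value=5.0),
        r_sign=st.sampled_from([-1.0, 0.0, 1.0]),
        b_sign=st.sampled_from([-1.0, 0.0, 1.0]),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_ec_exceeds_one_iff_growth_and_elasticity_share_sign(
        self, r_mag, b_mag, r_sign, b_sign
    ):
        r, b = r_sign * r_mag, b_sign * b_mag
        ec = effect_coefficient(r, b)
        if r == 0 or b == 0:
            assert ec == 1.0
        elif (r > 0) == (b > 0):
            assert ec > 1.0
        else:
            assert ec < 1.0


class TestContributionRates:
    def test_symmetric_two_factor_split(self):
        rates = contribution_rates({"a": 1.1, "b": 0.9}, r_squared=1.0)
        assert rates == {"a": pytest.approx(50.0), "b": pytest.approx(50.0)}

    def test_single_factor_scaled_by_r_squared(self):
        assert contribution_rates({"a": 1.2}, 0.5)["a"] == pytest.approx(50.0)

    def test_sum_equals_hundred_times_r_squared(self):
        ecs = {"a": 1.022, "b": 1.012, "c": 0.991, "d": 1.021}
        rates = contribution_rates(ecs, 0.940)
        assert sum(rates.values()) == pytest.approx(94.0)

    def test_published_inputs_give_formula_not_printed_rates(self):
        # the published table's own footnote formula yields ~33.2/17.7/12.8/30.4
        # (sum 94.0), not the printed 34.10/18.06/13.25/30.51 (sum 95.92)
        growth = {"population": 0.02352, "diet_choice": 0.00456,
                  "energy_intensity": -0.03527, "industrial_level": 0.00364}
        coefs = TRUE_COEFS
        ecs = {f: effect_coefficient(growth[f], coefs[f]) for f in coefs}
        rates = contribution_rates(ecs, 0.940)
        assert rates["population"] == pytest.approx(33.15, abs=0.1)
        assert rates["diet_choice"] == pytest.approx(17.67, abs=0.1)
        assert rates["energy_intensity"] == pytest.approx(12.80, abs=0.1)
        assert rates["industrial_level"] == pytest.approx(30.38, abs=0.1)
        assert sum(rates.values()) == pytest.approx(94.0)

    def test_invariant_to_factor_ordering(self):
        ecs = {"a": 1.03, "b": 0.97, "c": 1.10}
        flipped = dict(reversed(list(ecs.items())))
        assert contribution_rates(ecs, 0.8) == contribution_rates(flipped, 0.8)

    def test_all_unit_ecs_degenerate(self):
        with pytest.raises(DomainError):
            contribution_rates({"a": 1.0, "b": 1.0}, 0.9)


class TestDecomposeDrivers:
    def test_full_pipeline_on_synthetic_data(self):
        ds = simulate_stirpat_dataset(TRUE_COEFS, seed=0)
        deco = decompose_drivers(ds)
        assert sum(deco.contributions.values()) == pytest.approx(
            100.0 * deco.r_squared
        )
        table = deco.table
        assert list(table["factor"]) == list(TRUE_COEFS)
        assert (table["effect_coefficient"] > 0).all()


class TestScreenFactors:
    def test_identical_series_fully_correlated(self):
        s = [1.0, 2.0, 3.0, 4.5]
        corr, _vifs = screen_factors({"a": s, "b": s})
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(7)
        a = np.exp(rng.normal(size=1000))
        b = np.exp(rng.normal(size=1000))
        corr, _ = screen_factors({"a": a, "b": b})
        assert abs(corr.loc["a", "b"]) < 0.1

    def test_six_candidates_give_symmetric_unit_diagonal_matrix(self):
        rng = np.random.default_rng(1)
        candidates = {
            name: np.exp(rng.normal(size=21) * 0.2 + 1.0)
            for name in ("population", "diet", "per_capita", "energy_intensity",
                         "industrial_level", "industrial_structure")
        }
        corr, vifs = screen_factors(candidates)
        assert corr.shape == (6, 6)
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)
        assert set(vifs) == set(candidates)

    def test_constant_series_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            screen_factors({"a": [2.0, 2.0, 2.0], "b": [1.0, 2.0, 3.0]})
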