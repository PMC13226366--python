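"""Direct-standardization scenario engine."""

import numpy as np
import pandas as pd
import pytest

from caregap.exceptions import ConfigurationError, ValidationError
from caregap.projection import (
    ProjectionInputs,
    ScenarioSpec,
    caregiver_distribution,
    expand_population,
    pct_increase,
    project_counts,
    round_half_up,
    run_scenario,
    run_scenario_suite,
    expand_population,
)
from caregap import fixtures


def toy_inputs(p_by_stratum, shares_by_year, totals=None, outcome="y"):
    strata = list(p_by_stratum)
    shares = pd.DataFrame(shares_by_year, index=strata)
    probs = pd.DataFrame({outcome: [p_by_stratum[g] for g in strata]}, index=strata)
    overall = pd.DataFrame(
        {outcome: [(shares[2022] * probs[outcome]).sum()]}, index=["overall"]
    )
    return ProjectionInputs(
        totals=totals or {2022: 50.0, 2030: 60.0, 2040: 62.0},
        shares={
            "g": shares,
            "overall": pd.DataFrame({y: [1.0] for y in shares.columns}, index=["overall"]),
        },
        probabilities={"g": probs, "overall": overall},
    )


class TestProjectCounts:
    def test_growth_only_uses_overall_rate(self):
        inputs = fixtures.benchmark_inputs()
        spec = ScenarioSpec(outcome="no_family_caregiver")
        assert project_counts(inputs, spec, 2040) == pytest.approx(62.1 * 0.110, abs=1e-9)

    def test_age_standardized_2040_count(self):
        inputs = fixtures.benchmark_inputs()
        spec = ScenarioSpec(outcome="no_family_caregiver", factor="age_group")
        expected = 62.1 * (0.417 * 0.094 + 0.390 * 0.129 + 0.193 * 0.133)
        assert project_counts(inputs, spec, 2040) == pytest.approx(expected, rel=1e-6)

    def test_uniform_probabilities_collapse_onto_growth_only(self):
        shares = {2022: [0.5, 0.3, 0.2], 2030: [0.2, 0.3, 0.5], 2040: [0.1, 0.1, 0.8]}
        inputs = toy_inputs({"a": 0.11, "b": 0.11, "c": 0.11}, shares)
        for year in (2022, 2030, 2040):
            growth = project_counts(inputs, ScenarioSpec("y"), year)
            factor = project_counts(inputs, ScenarioSpec("y", factor="g"), year)
            assert factor == pytest.approx(growth, abs=1e-12)

    def test_linearity_in_totals(self):
        shares = {2022: [0.6, 0.4], 2040: [0.3, 0.7]}
        inputs = toy_inputs({"a": 0.2, "b": 0.05}, shares, totals={2022: 10.0, 2040: 20.0})
        doubled = ProjectionInputs(
            totals={y: 2 * t for y, t in inputs.totals.items()},
            shares=inputs.shares,
            probabilities=inputs.probabilities,
        )
        spec = ScenarioSpec("y", factor="g")
        assert project_counts(doubled, spec, 2040) == pytest.approx(
            2 * project_counts(inputs, spec, 2040), abs=1e-12
        )

    def test_no_family_caregiver_is_sum_of_none_and_paid_only(self):
        inputs = fixtures.benchmark_inputs()
        for factor in (None, "age_group", "family_structure", "family_size"):
            for year in (2022, 2030, 2040):
                total = project_counts(
                    inputs, ScenarioSpec("no_family_caregiver", factor=factor), year
                )
                none = project_counts(inputs, ScenarioSpec("none", factor=factor), year)
                paid = project_counts(
                    inputs, ScenarioSpec("paid_only", factor=factor), year
                )
                assert total == pytest.approx(none + paid, abs=1e-12)

    def test_missing_stratum_probability_is_a_named_error(self):
        shares = {2022: [0.6, 0.4], 2040: [0.3, 0.7]}
        inputs = toy_inputs({"a": 0.2, "b": 0.05}, shares, totals={2022: 10.0, 2040: 20.0})
        inputs.probabilities["g"].loc["b", "y"] = np.nan
        with pytest.raises(ConfigurationError, match="'b'"):
            project_counts(inputs, ScenarioSpec("y", factor="g"), 2040)

    def test_matches_scalar_loop_oracle_on_random_inputs(self, rng):
        for _ in range(25):
            strata = [f"s{i}" for i in range(4)]
            shares = {
                year: rng.dirichlet(np.ones(4)) for year in (2022, 2030, 2040)
            }
            p = {g: float(rng.random()) for g in strata}
            inputs = toy_inputs(p, shares)
            year = int(rng.choice([2022, 2030, 2040]))
            spec = ScenarioSpec("y", factor="g")
            vectorized = project_counts(inputs, spec, year)
            oracle = 0.0
            for k, g in enumerate(strata):  # scalar per-stratum loop
                oracle += inputs.totals[year] * shares[year][k] * p[g]
            assert vectorized == pytest.approx(oracle, abs=1e-12)


class TestPctIncrease:
    def test_hand_computations(self):
        assert pct_increase({2022: 2.0, 2040: 3.0}) == pytest.approx(50.0)
        assert pct_increase({2022: 5.0, 2040: 5.0}) == pytest.approx(0.0)

    def test_age_scenario_increase_from_benchmark(self):
        inputs = fixtures.benchmark_inputs()
        result = run_scenario(inputs, ScenarioSpec("no_family_caregiver", factor="age_group"))
        assert result.pct_increase == pytest.approx(29.3, abs=0.1)

    def test_zero_baseline_reported_missing(self):
        with pytest.warns(UserWarning, match="zero baseline"):
            assert pct_increase({2022: 0.0, 2040: 1.0}) is None


class TestExpandPopulation:
    def test_fraction_zero_is_identity(self):
        inputs = fixtures.benchmark_inputs()
        expanded = expand_population(inputs, fraction=0.0)
        assert expanded.totals == inputs.totals

    def test_twenty_percent_expansion_of_2022_total(self):
        inputs = fixtures.benchmark_inputs()
        expanded = expand_population(inputs, fraction=0.20)
        assert expanded.totals[2022] == pytest.approx(50.5 / 0.8)

    def test_fraction_one_rejected(self):
        with pytest.raises(ValidationError):
            expand_population(fixtures.benchmark_inputs(), fraction=1.0)

    def test_explicit_totals_ratio_scaling(self):
        # alternative population: growth-only scales the 2022 baseline by the
        # total ratio, 6.3 * 77.2 / 62.8 ~= 7.7 million in 2040
        totals = dict(fixtures.ALTERNATIVE_TOTALS)
        baseline = fixtures.ALTERNATIVE_BASELINES_2022["no_family_caregiver"]
        rate = baseline / totals[2022]
        inputs = ProjectionInputs(
            totals=totals,
            shares={"overall": pd.DataFrame({y: [1.0] for y in totals}, index=["overall"])},
            probabilities={"overall": pd.DataFrame({"no_family_caregiver": [rate]}, index=["overall"])},
        )
        count = project_counts(inputs, ScenarioSpec("no_family_caregiver"), 2040)
        assert round_half_up(count) == pytest.approx(7.7)

    def test_requires_exactly_one_mode(self):
        inputs = fixtures.benchmark_inputs()
        with pytest.raises(ValidationError):
            expand_population(inputs)
        with pytest.raises(ValidationError):
            expand_population(inputs, totals={2022: 1.0}, fraction=0.1)


class TestCaregiverDistribution:
    @staticmethod
    def category_inputs(tables, shares_by_year):
        strata = list(next(iter(tables.values())).keys()) if False else None
        frame = pd.DataFrame(tables).T
        shares = pd.DataFrame(shares_by_year, index=frame.index)
        return ProjectionInputs(
            totals={2022: 10.0, 2040: 12.0},
            shares={"g": shares},
            probabilities={"g": frame},
        )

    def test_single_stratum_equals_renormalized_probabilities(self):
        tables = {
            "a": {"none": 0.10, "paid_only": 0.02, "fam1": 0.15, "fam2": 0.08, "fam3plus": 0.05},
        }
        inputs = self.category_inputs(tables, {2022: [1.0], 2040: [1.0]})
        dist, mean = caregiver_distribution(inputs, None, 2022, stratifier="g")
        total = sum(tables["a"].values())
        for k, v in tables["a"].items():
            assert dist[k] == pytest.approx(100 * v / total)
        assert dist.sum() == pytest.approx(100.0, abs=1e-9)
        expected_mean = (0.15 * 1 + 0.08 * 2 + 0.05 * 3) / total
        assert mean == pytest.approx(expected_mean)

    def test_two_stratum_hand_enumeration(self):
        tables = {
            "a": {"none": 0.2, "paid_only": 0.0, "fam1": 0.1, "fam2": 0.1, "fam3plus": 0.0},
            "b": {"none": 0.05, "paid_only": 0.05, "fam1": 0.2, "fam2": 0.0, "fam3plus": 0.1},
        }
        inputs = self.category_inputs(tables, {2022: [0.25, 0.75], 2040: [0.5, 0.5]})
        dist, mean = caregiver_distribution(inputs, "g", 2040)
        masses = {
            k: 0.5 * tables["a"][k] + 0.5 * tables["b"][k]
            for k in tables["a"]
        }
        total = sum(masses.values())
        for k in masses:
            assert dist[k] == pytest.approx(100 * masses[k] / total)
        expected = (masses["fam1"] + 2 * masses["fam2"] + 3 * masses["fam3plus"]) / total
        assert mean == pytest.approx(expected)

    def test_include_paid_flag_raises_mean(self):
        tables = {
            "a": {"none": 0.1, "paid_only": 0.1, "fam1": 0.1, "fam2": 0.0, "fam3plus": 0.0},
        }
        inputs = self.category_inputs(tables, {2022: [1.0], 2040: [1.0]})
        _, mean_without = caregiver_distribution(inputs, None, 2022, stratifier="g")
        _, mean_with = caregiver_distribution(
            inputs, None, 2022, stratifier="g", include_paid=True
        )
        assert mean_with > mean_without


class TestScenarioSuite:
    def test_suite_shape_and_subgroup_consistency(self):
        inputs = fixtures.benchmark_inputs()
        single = run_scenario_suite(inputs)
        assert single.shape == (8, 4)
        paired = run_scenario_suite({"overall_a": inputs, "overall_b": inputs})
        a = paired.xs("overall_a", level="subgroup")
        b = paired.xs("overall_b", level="subgroup")
        pd.testing.assert_frame_equal(a, b)

    def test_every_cell_matches_scalar_recomputation(self):
        inputs = fixtures.benchmark_inputs()
        suite = run_scenario_suite(inputs)
        factor_for_label = {
            "Population growth only": None,
            "& Age structure": "age_group",
            "& Family structure": "family_structure",
            "& Family size": "family_size",
        }
        for (outcome, label), row in suite.iterrows():
            factor = factor_for_label[label]
            strat = factor or "overall"
            p = inputs.probability_vector(strat, outcome)
            for year in (2022, 2030, 2040):
                share_year = 2022 if factor is None else year
                s = inputs.shares[strat][share_year]
                oracle = 0.0
                for g in s.index:  # scalar loop
                    oracle += inputs.totals[year] * s[g] * p[g]
                assert row[year] == pytest.approx(oracle, abs=1e-12)


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(5.55) == 5.6
    assert round_half_up(6.25) == 6.3
    assert round_half_up(-5.55) == -5.6
    assert round_half_up(7.1499) == 7.1
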