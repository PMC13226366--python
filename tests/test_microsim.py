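"""Kinship microsimulation: event mechanics, classification, tabulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from caregap.codes import AGE_BIN_EDGES, family_size_label, family_structure_code
from caregap.exceptions import ConfigurationError, ValidationError
from caregap.microsim import (
    Agent,
    Population,
    RateSchedule,
    SimConfig,
    classify_family_structure,
    compute_family_size,
    run_simulation,
    scale_to_totals,
    step_year,
    tabulate_kin,
)

from conftest import add_child, make_agent, marry_agents


def copy_state(population):
    return {
        a.id: (a.death_year, a.married, frozenset(a.bio_children), frozenset(a.step_children))
        for a in population
    }


class TestRateSchedule:
    def test_missing_cell_raises_named_configuration_error(self):
        rates = RateSchedule(mortality={("White", 100, "female"): 1.0})
        with pytest.raises(ConfigurationError, match=r"\('White', 40, 'female'\)"):
            rates.mortality_at("White", 40, "female")

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValidationError):
            RateSchedule(mortality={("White", 50, "female"): 1.5})

    def test_mortality_must_be_one_at_age_cap(self):
        with pytest.raises(ValidationError, match="must be 1"):
            RateSchedule(mortality={("White", 100, "female"): 0.5})

    def test_csv_round_trip(self, tmp_path):
        df = pd.DataFrame(
            [
                {"event": "mortality", "race": "White", "sex": "female",
                 "age_or_duration": 70, "parity": "", "marital_status": "",
                 "probability": 0.02},
                {"event": "divorce", "race": "White", "sex": "",
                 "age_or_duration": 3, "parity": "", "marital_status": "",
                 "probability": 0.01},
                {"event": "fertility", "race": "White", "sex": "female",
                 "age_or_duration": 30, "parity": 1, "marital_status": "married",
                 "probability": 0.15},
            ]
        )
        path = tmp_path / "rates.csv"
        df.to_csv(path, index=False)
        rates = RateSchedule.from_csv(str(path), fill={"marriage": 0.0})
        assert rates.mortality_at("White", 70, "female") == 0.02
        assert rates.divorce_at("White", 3) == 0.01
        assert rates.fertility_at("White", 30, 1, "married") == 0.15
        assert rates.marriage_at("White", 30, "female", False) == 0.0


class TestStepYear:
    def test_zero_rates_leave_population_unchanged(self, rng):
        population = Population(
            [make_agent(i, birth_year=1960 + i % 30) for i in range(50)]
        )
        before = copy_state(population)
        step_year(population, RateSchedule.constant(), 2020, rng)
        assert copy_state(population) == before

    def test_age_cap_no_survivor_beyond_100(self, rng):
        population = Population([make_agent(0, birth_year=1920)])  # age 100 in 2020
        step_year(population, RateSchedule.constant(), 2020, rng)
        assert not population[0].alive(2020)

    def test_flat_mortality_matches_binomial_oracle(self, rng):
        n, p = 10_000, 0.1
        population = Population([make_agent(i, birth_year=1970) for i in range(n)])
        step_year(population, RateSchedule.constant(mortality=p), 2020, rng)
        deaths = sum(1 for a in population if not a.alive(2020))
        lo, hi = stats.binom.interval(0.999, n, p)
        assert lo <= deaths <= hi

    def test_widowhood_closes_both_union_records(self, rng):
        population = Population([make_agent(0), make_agent(1, sex="male")])
        marry_agents(population, population[0], population[1], 2000)
        step_year(population, RateSchedule.constant(mortality=1.0), 2020, rng)
        for agent in population:
            union = agent.unions[-1]
            assert union.end_year == 2020
            assert union.end_reason == "widowhood"

    def test_marriage_creates_symmetric_step_ties(self, rng):
        population = Population([make_agent(0), make_agent(1, sex="male")])
        child = add_child(population, [population[0]], 2, 1980)
        rates = RateSchedule.constant(marriage=1.0)
        step_year(population, rates, 2000, rng)
        husband = population[1]
        assert husband.married and population[0].married
        assert child.id in husband.step_children
        assert husband.id in child.step_parents
        assert child.id not in husband.bio_children

    def test_newborn_links_to_mother_and_spouse(self, rng):
        population = Population([make_agent(0, birth_year=1990),
                                 make_agent(1, sex="male", birth_year=1990)])
        marry_agents(population, population[0], population[1], 2018)
        rates = RateSchedule.constant(fertility=1.0)
        step_year(population, rates, 2020, rng)
        babies = [a for a in population if a.birth_year == 2020]
        assert len(babies) == 1
        baby = babies[0]
        assert baby.parents == {0, 1}
        assert baby.id in population[0].bio_children
        assert baby.id in population[1].bio_children

    def test_nonmarital_birth_has_single_parent(self, rng):
        population = Population([make_agent(0, birth_year=1990)])
        step_year(population, RateSchedule.constant(fertility=1.0), 2020, rng)
        baby = [a for a in population if a.birth_year == 2020][0]
        assert baby.parents == {0}


@pytest.mark.parametrize(
    "married, n_bio, n_step, expected",
    [
        (False, 0, 0, "U0"),
        (False, 3, 0, "UB"),
        (False, 0, 1, "US"),
        (True, 0, 0, "M0"),
        (True, 2, 0, "MB"),
        (True, 2, 1, "MS"),  # any stepchildren dominate biological-only
        (False, 2, 1, "US"),
    ],
)
def test_family_structure_codes(married, n_bio, n_step, expected):
    assert family_structure_code(married, n_bio, n_step) == expected


@pytest.mark.parametrize(
    "married, n_bio, n_step, expected",
    [
        (True, 1, 0, "2"),   # spouse counts toward family size
        (False, 0, 0, "0"),
        (True, 3, 2, "4+"),  # capped at 4 or more
        (False, 3, 0, "3"),
    ],
)
def test_family_size_labels(married, n_bio, n_step, expected):
    assert family_size_label(married, n_bio, n_step) == expected


class TestTabulation:
    def test_single_agent_lands_in_expected_cell(self):
        population = Population([make_agent(0, birth_year=1952),
                                 make_agent(1, sex="male", birth_year=1952)])
        for cid in (2, 3):
            add_child(population, [population[0], population[1]], cid, 1980)
        marry_agents(population, population[0], population[1], 1975)
        tab = tabulate_kin(population, 2022)
        # the 70-year-old spouses: both MB with family size 3
        assert tab.data[("65-74", "female", "White", "MB", "3")] == 1.0
        assert tab.data[("65-74", "male", "White", "MB", "3")] == 1.0
        assert tab.total() == 2.0

    def test_masses_match_per_agent_brute_force_recount(self, random_kin_population):
        population = random_kin_population
        year = 2022
        tab = tabulate_kin(population, year)

        # independent loop oracle: recount each agent from raw kin links
        expected: dict[tuple, float] = {}
        n_expected = 0
        for agent in population:
            if not agent.alive(year):
                continue
            age = year - agent.birth_year
            if age < 65:
                continue
            group = "65-74" if age < 75 else "75-84" if age < 85 else "85+"
            married = any(u.end_year is None for u in agent.unions)
            n_bio = sum(1 for c in agent.bio_children if population[c].alive(year))
            n_step = sum(1 for c in agent.step_children if population[c].alive(year))
            if n_step > 0:
                code = ("M" if married else "U") + "S"
            elif n_bio > 0:
                code = ("M" if married else "U") + "B"
            else:
                code = ("M" if married else "U") + "0"
            size = min(int(married) + n_bio + n_step, 4)
            size_label = "4+" if size == 4 else str(size)
            key = (group, agent.sex, agent.race, code, size_label)
            expected[key] = expected.get(key, 0.0) + 1.0
            n_expected += 1

        assert tab.total() == n_expected
        nonzero = tab.data[tab.data > 0]
        assert dict(nonzero.items()) == expected

    def test_structure_size_coherence(self, random_kin_population):
        tab = tabulate_kin(random_kin_population, 2022)
        frame = tab.to_frame()
        occupied = frame[frame["mass"] > 0]
        for row in occupied.itertuples(index=False):
            if row.family_structure == "U0":
                assert row.family_size == "0"
            else:
                assert row.family_size != "0"
            if row.family_structure == "M0":
                assert row.family_size == "1"

    def test_empty_population_warns_and_returns_zero(self):
        population = Population([make_agent(0, birth_year=2000)])
        with pytest.warns(UserWarning, match="65"):
            tab = tabulate_kin(population, 2022)
        assert tab.total() == 0.0

    def test_nonstandard_age_bins_rejected(self):
        with pytest.raises(ConfigurationError):
            tabulate_kin(Population(), 2022, age_bins=(65, 80, 101))


class TestScaling:
    def test_scale_to_millions(self, random_kin_population):
        tab = tabulate_kin(random_kin_population, 2022)
        scaled = scale_to_totals(tab, 50.5)
        assert scaled.total() == pytest.approx(50.5, abs=1e-12)

    def test_scaling_to_own_total_is_identity(self, random_kin_population):
        tab = tabulate_kin(random_kin_population, 2022)
        scaled = scale_to_totals(tab, tab.total())
        pd.testing.assert_series_equal(scaled.data, tab.data)

    def test_shares_invariant_under_scaling(self, random_kin_population):
        tab = tabulate_kin(random_kin_population, 2022)
        scaled = scale_to_totals(tab, 62.1)
        for level in ("age_group", "family_structure", "family_size"):
            before = tab.shares(level)
            after = scaled.shares(level)
            assert np.allclose(before.to_numpy(), after.to_numpy(), atol=1e-12)

    def test_zero_total_cannot_scale(self):
        population = Population([make_agent(0, birth_year=2000)])
        with pytest.warns(UserWarning):
            tab = tabulate_kin(population, 2022)
        with pytest.raises(ValidationError):
            scale_to_totals(tab, 50.0)


class TestRunSimulation:
    @staticmethod
    def small_config(seed=3, rates=None, years=30):
        initial = {(age, sex, race): 25
                   for age in (25, 35, 45, 55, 65)
                   for sex in ("female", "male")
                   for race in ("White", "Black")}
        return SimConfig(
            start_year=2000,
            end_year=2000 + years,
            rates=rates or RateSchedule.stylized(),
            initial=initial,
            random_seed=seed,
            output_years=(2000 + years,),
        )

    def test_same_seed_gives_identical_tabulations(self):
        tabs_a = run_simulation(self.small_config())
        tabs_b = run_simulation(self.small_config())
        for year in tabs_a:
            pd.testing.assert_series_equal(tabs_a[year].data, tabs_b[year].data)

    def test_zero_rates_shift_ages_only(self):
        config = SimConfig(
            start_year=2017,
            end_year=2022,
            rates=RateSchedule.constant(),
            initial={(62, "female", "White"): 10, (72, "male", "Black"): 5},
            random_seed=0,
            output_years=(2022,),
        )
        tabs = run_simulation(config)
        tab = tabs[2022]
        # everyone aged by 5 years, nothing else changed
        assert tab.data[("65-74", "female", "White", "U0", "0")] == 10
        assert tab.data[("75-84", "male", "Black", "U0", "0")] == 5
        assert tab.total() == 15

    def test_population_nonincreasing_without_fertility(self, rng):
        population = Population([make_agent(i, birth_year=1950 + i % 40) for i in range(200)])
        rates = RateSchedule.constant(mortality=0.05, marriage=0.1)
        sizes = [len(population.living(2000))]
        for year in range(2001, 2021):
            step_year(population, rates, year, rng)
            sizes.append(len(population.living(year)))
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_marriage_share_matches_aggregate_oracle(self):
        """With only marriage active, the agent-level simulator must agree
        with an independent aggregate (binomial-counts) re-implementation."""
        n_each, p, years = 1500, 0.08, 12
        population = Population(
            [make_agent(i, sex="female", birth_year=1980) for i in range(n_each)]
            + [make_agent(n_each + i, sex="male", birth_year=1980) for i in range(n_each)]
        )
        rates = RateSchedule.constant(marriage=p)
        rng = np.random.default_rng(11)
        for year in range(2011, 2011 + years):
            step_year(population, rates, year, rng)
        married = sum(1 for a in population if a.married) / (2 * n_each)

        # aggregate oracle: per year, binomial candidates per sex, matches = min
        oracle_rng = np.random.default_rng(12)
        reps = []
        for _ in range(200):
            single_f, single_m, wed = n_each, n_each, 0
            for _ in range(years):
                cf = oracle_rng.binomial(single_f, p)
                cm = oracle_rng.binomial(single_m, p)
                matched = min(cf, cm)
                single_f -= matched
                single_m -= matched
                wed += 2 * matched
            reps.append(wed / (2 * n_each))
        mean, sd = float(np.mean(reps)), float(np.std(reps))
        assert abs(married - mean) < 4 * sd + 1e-9


class TestInvariants:
    def test_kin_symmetry_conservation_and_determinism(self):
        config = TestRunSimulation.small_config(seed=9, years=30)
        from caregap.microsim import build_initial_population

        population = build_initial_population(config)
        rng = np.random.default_rng(config.random_seed)
        for year in range(config.start_year + 1, config.end_year + 1):
            before_ids = {a.id for a in population.living(year - 1)}
            step_year(population, config.rates, year, rng)
            # conservation: previous living either survive or died this year
            survivors = {a.id for a in population.living(year)} & before_ids
            deaths = {a.id for a in population if a.death_year == year}
            assert survivors | deaths >= before_ids

        for agent in population:
            assert agent.death_year is None or agent.death_year >= agent.birth_year
            for child_id in agent.bio_children:
                assert agent.id in population[child_id].parents
            for child_id in agent.step_children:
                assert agent.id in population[child_id].step_parents
            assert not (agent.bio_children & agent.step_children)
            # monogamy: unions do not overlap in time
            spans = sorted(
                (u.start_year, u.end_year if u.end_year is not None else 10**9)
                for u in agent.unions
            )
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                assert e1 <= s2
            if agent.death_year is None:
                assert agent.age(config.end_year) <= 100
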