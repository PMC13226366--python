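import numpy as np
import pytest

from caregap.microsim import Agent, Population, UnionRecord
from caregap.records import ActivityRecord, Helper, SurveyRespondent


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_agent(agent_id, *, sex="female", race="White", birth_year=1950, **kwargs):
    return Agent(id=agent_id, sex=sex, race=race, birth_year=birth_year, **kwargs)


def marry_agents(population, a, b, year):
    """Create a symmetric union (and step ties) outside the simulator."""
    a.unions.append(UnionRecord(partner_id=b.id, start_year=year))
    b.unions.append(UnionRecord(partner_id=a.id, start_year=year))
    a.ever_married = b.ever_married = True
    for parent, spouse in ((a, b), (b, a)):
        for child_id in parent.bio_children:
            if child_id not in spouse.bio_children:
                spouse.step_children.add(child_id)
                population[child_id].step_parents.add(spouse.id)


def add_child(population, parents, child_id, birth_year):
    child = Agent(
        id=child_id,
        sex="female",
        race=parents[0].race,
        birth_year=birth_year,
    )
    population.add(child)
    for parent in parents:
        parent.bio_children.add(child.id)
        child.parents.add(parent.id)
    return child


@pytest.fixture
def random_kin_population(rng):
    """~500 agents aged 30-100 with random marriages and children."""
    population = Population()
    n_adults = 360
    for i in range(n_adults):
        population.add(
            Agent(
                id=i,
                sex="female" if rng.random() < 0.5 else "male",
                race="White" if rng.random() < 0.8 else "Black",
                birth_year=2022 - int(rng.integers(30, 101)),
            )
        )
    next_id = n_adults
    adults = list(population)
    females = [a for a in adults if a.sex == "female"]
    males = [a for a in adults if a.sex == "male"]
    for wife, husband in zip(females, males):
        if rng.random() < 0.6 and wife.race == husband.race:
            # children born before the union become stepchildren of the spouse
            for _ in range(int(rng.integers(0, 3))):
                add_child(population, [wife], next_id, wife.birth_year + 25)
                next_id += 1
            marry_agents(population, wife, husband, 2000)
            for _ in range(int(rng.integers(0, 3))):
                add_child(population, [wife, husband], next_id, 2001)
                next_id += 1
    return population


def respondent(
    rid=0,
    *,
    weight=1.0,
    activities=None,
    consequences=None,
    married=False,
    n_bio=0,
    n_step=0,
    **kwargs,
):
    return SurveyRespondent(
        id=rid,
        weight=weight,
        age_group=kwargs.pop("age_group", "65-74"),
        sex=kwargs.pop("sex", "female"),
        race=kwargs.pop("race", "White"),
        married=married,
        n_bio=n_bio,
        n_step=n_step,
        activities=activities or [],
        consequences=consequences if consequences is not None else [False] * 5,
    )


def helped(activity, relationship, paid=False, helper_id=None, reason=None, difficulty=True):
    return ActivityRecord(
        activity,
        difficulty=difficulty,
        helpers=[Helper(relationship, paid=paid, helper_id=helper_id)],
        reason=reason,
    )
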