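"""Discrete-time kinship-network microsimulation.

Simulates annual demographic events — mortality, divorce, marriage and
remarriage, fertility — over a closed population of individually
represented agents, maintaining a kinship network of spouses, biological
children and stepchildren.  The 65+ population is tabulated by age group,
sex, race, family structure and family size, and scaled to externally
supplied totals (millions), yielding the compositional margins the
projection engine standardizes over.

Design conventions (the source being silent on most of them):

* Events within a year apply in a fixed order: mortality, then divorce,
  then marriage/remarriage, then fertility.  Ages are completed years,
  ``year - birth_year``, with a hard cap at 100 (mortality is forced to 1
  at the cap).
* White and Black populations are closed and separate: spouses are drawn
  within race and there is no migration.
* On marriage each partner's biological children become the new spouse's
  stepchildren (symmetrically recorded on the child as a step-parent);
  step ties persist after divorce or widowhood.
* Births attach to women; the current spouse, if any, becomes biological
  co-parent.  Nonmarital births have a single linked parent.
* Family structure/size in a given year count only children alive that
  year.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .codes import (
    AGE_BIN_EDGES,
    AGE_GROUPS,
    FAMILY_SIZE_LABELS,
    FAMILY_STRUCTURES,
    MAX_AGE,
    RACES,
    SEXES,
    FEMALE,
    MALE,
    family_size_label,
    family_structure_code,
)
from .exceptions import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

DIVORCE = "divorce"
WIDOWHOOD = "widowhood"
ONGOING = "ongoing"

MARRIED = "married"
UNMARRIED = "unmarried"

#: Parity categories above this value share the top fertility rate cell.
PARITY_CAP = 4


@dataclass
class UnionRecord:
    partner_id: int
    start_year: int
    end_year: int | None = None
    end_reason: str = ONGOING

    def active(self) -> bool:
        return self.end_year is None


@dataclass
class Agent:
    id: int
    sex: str
    race: str
    birth_year: int
    death_year: int | None = None
    unions: list[UnionRecord] = field(default_factory=list)
    bio_children: set[int] = field(default_factory=set)
    step_children: set[int] = field(default_factory=set)
    parents: set[int] = field(default_factory=set)
    step_parents: set[int] = field(default_factory=set)
    ever_married: bool = False

    def age(self, year: int) -> int:
        return year - self.birth_year

    def alive(self, year: int) -> bool:
        return self.birth_year <= year and (self.death_year is None or self.death_year > year)

    def current_union(self) -> UnionRecord | None:
        for union in reversed(self.unions):
            if union.active():
                return union
        return None

    @property
    def married(self) -> bool:
        return self.current_union() is not None


class Population:
    """Agent container with id allocation and kin-link bookkeeping."""

    def __init__(self, agents: Iterable[Agent] = ()):
        self.agents: dict[int, Agent] = {}
        for agent in agents:
            self.add(agent)

    def add(self, agent: Agent) -> Agent:
        if agent.id in self.agents:
            raise ValidationError(f"duplicate agent id {agent.id}")
        self.agents[agent.id] = agent
        return agent

    def new_id(self) -> int:
        return max(self.agents, default=-1) + 1

    def __getitem__(self, agent_id: int) -> Agent:
        return self.agents[agent_id]

    def __len__(self) -> int:
        return len(self.agents)

    def __iter__(self):
        return iter(self.agents.values())

    def living(self, year: int) -> list[Agent]:
        return [a for a in self.agents.values() if a.alive(year)]

    def living_children(self, agent: Agent, year: int) -> tuple[int, int]:
        n_bio = sum(1 for c in agent.bio_children if self.agents[c].alive(year))
        n_step = sum(1 for c in agent.step_children if self.agents[c].alive(year))
        return n_bio, n_step


@dataclass
class RateSchedule:
    """Annual event probabilities.

    mortality:   (race, age, sex) -> p         [required at every living age;
                                                must equal 1 at age 100]
    marriage:    (race, age, sex) -> p         [first marriage]
    remarriage:  (race, age, sex) -> p         [after divorce/widowhood;
                                                falls back to marriage]
    divorce:     (race, duration) -> p
    fertility:   (race, age, parity, marital_status) -> p, women only;
                 parity capped at 4.

    ``fill`` values, when given, stand in for missing cells of the
    non-mortality tables; otherwise a missing lookup raises a
    :class:`ConfigurationError` naming the cell.
    """

    mortality: dict[tuple, float]
    marriage: dict[tuple, float] = field(default_factory=dict)
    remarriage: dict[tuple, float] | None = None
    divorce: dict[tuple, float] = field(default_factory=dict)
    fertility: dict[tuple, float] = field(default_factory=dict)
    fill: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for name in ("mortality", "marriage", "remarriage", "divorce", "fertility"):
            table = getattr(self, name)
            if table is None:
                continue
            for cell, p in table.items():
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(
                        f"{name} probability {p!r} at cell {cell} outside [0, 1]"
                    )
        for race in RACES:
            for sex in SEXES:
                cell = (race, MAX_AGE, sex)
                if cell in self.mortality and self.mortality[cell] != 1.0:
                    raise ValidationError(
                        f"mortality at age {MAX_AGE} must be 1 (cell {cell})"
                    )

    def _lookup(self, name: str, table: dict, cell: tuple) -> float:
        if cell in table:
            return table[cell]
        if self.fill is not None and name in self.fill:
            return self.fill[name]
        raise ConfigurationError(f"missing {name} rate for cell {cell}")

    def mortality_at(self, race: str, age: int, sex: str) -> float:
        if age >= MAX_AGE:
            return 1.0
        return self._lookup("mortality", self.mortality, (race, age, sex))

    def marriage_at(self, race: str, age: int, sex: str, ever_married: bool) -> float:
        if ever_married:
            table = self.remarriage if self.remarriage is not None else self.marriage
            name = "remarriage" if self.remarriage is not None else "marriage"
        else:
            table, name = self.marriage, "marriage"
        return self._lookup(name, table, (race, age, sex))

    def divorce_at(self, race: str, duration: int) -> float:
        return self._lookup("divorce", self.divorce, (race, duration))

    def fertility_at(self, race: str, age: int, parity: int, marital_status: str) -> float:
        cell = (race, age, min(parity, PARITY_CAP), marital_status)
        return self._lookup("fertility", self.fertility, cell)

    # -- constructors -------------------------------------------------------

    @classmethod
    def constant(
        cls,
        mortality: float = 0.0,
        marriage: float = 0.0,
        divorce: float = 0.0,
        fertility: float = 0.0,
    ) -> "RateSchedule":
        """Flat schedule (handy for tests and stylized runs)."""
        table = {
            (race, MAX_AGE, sex): 1.0 for race in RACES for sex in SEXES
        }
        return cls(
            mortality=table,
            fill={
                "mortality": mortality,
                "marriage": marriage,
                "remarriage": marriage,
                "divorce": divorce,
                "fertility": fertility,
            },
        )

    @classmethod
    def stylized(cls) -> "RateSchedule":
        """A demonstrative schedule with age-graded rates.

        Gompertz-like adult mortality, bell-shaped marriage hazard peaking
        in the late twenties, duration-declining divorce, and fertility
        concentrated at ages 20-39 with a marital premium.  Intended for
        desk-scale experiments, not calibrated to any national series.
        """
        mortality, marriage, divorce, fertility = {}, {}, {}, {}
        for race in RACES:
            black = race == "Black"
            for age in range(0, MAX_AGE + 1):
                # Gompertz-like adult hazard: ~0.001 at 50, ~0.1 at 80, ~0.4 at 95.
                base = 5e-5 * np.exp(age / 10.5) if age >= 30 else 0.002 - age * 4e-5
                base *= 1.15 if black else 1.0
                for sex in SEXES:
                    q = base * (1.25 if sex == MALE else 1.0)
                    mortality[(race, age, sex)] = float(min(q, 1.0)) if age < MAX_AGE else 1.0
                if 18 <= age <= 80:
                    m = 0.25 * np.exp(-(((age - 26) / 14.0) ** 2))
                    for sex in SEXES:
                        marriage[(race, age, sex)] = float(m)
                if 15 <= age <= 49:
                    f = 0.28 * np.exp(-(((age - 27) / 8.5) ** 2))
                    for parity in range(PARITY_CAP + 1):
                        scale = 1.0 / (1.0 + 0.25 * parity)
                        fertility[(race, age, parity, MARRIED)] = float(f * scale)
                        fertility[(race, age, parity, UNMARRIED)] = float(0.4 * f * scale)
            for duration in range(0, 83):
                divorce[(race, duration)] = float(0.03 * np.exp(-duration / 20.0))
        return cls(
            mortality=mortality,
            marriage=marriage,
            divorce=divorce,
            fertility=fertility,
            fill={"marriage": 0.0, "remarriage": 0.0, "divorce": 0.0, "fertility": 0.0},
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fill: Mapping[str, float] | None = None) -> "RateSchedule":
        """Long-format table with columns event, race, sex, age_or_duration,
        parity, marital_status, probability."""
        required = {"event", "race", "age_or_duration", "probability"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"rate table missing columns {sorted(missing)}")
        tables: dict[str, dict] = {
            "mortality": {}, "marriage": {}, "remarriage": {}, "divorce": {}, "fertility": {}
        }
        for row in df.itertuples(index=False):
            event = row.event
            if event not in tables:
                raise ValidationError(f"unknown event {event!r} in rate table")
            age = int(row.age_or_duration)
            p = float(row.probability)
            if event == "divorce":
                cell = (row.race, age)
            elif event == "fertility":
                cell = (row.race, age, int(row.parity), row.marital_status)
            else:
                cell = (row.race, age, row.sex)
            tables[event][cell] = p
        remarriage = tables["remarriage"] or None
        return cls(
            mortality=tables["mortality"],
            marriage=tables["marriage"],
            remarriage=remarriage,
            divorce=tables["divorce"],
            fertility=tables["fertility"],
            fill=fill,
        )

    @classmethod
    def from_csv(cls, path: str, fill: Mapping[str, float] | None = None) -> "RateSchedule":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False), fill=fill)


# ---------------------------------------------------------------------------
# Annual step
# ---------------------------------------------------------------------------

def step_year(
    population: Population,
    rates: RateSchedule,
    year: int,
    rng: np.random.Generator,
    age_gap_mean: float = 2.0,
    age_gap_sd: float = 3.0,
) -> Population:
    """Apply one year of demographic events in place.

    Order: mortality -> divorce -> marriage/remarriage -> fertility.
    Grooms are matched within race by target age ``bride age +
    Normal(age_gap_mean, age_gap_sd)`` truncated to [18, 100].
    """
    living = sorted(population.living(year), key=lambda a: a.id)

    # 1. Mortality (closing the survivor's union as widowhood).
    for agent in living:
        p = rates.mortality_at(agent.race, agent.age(year), agent.sex)
        if rng.random() < p:
            agent.death_year = year
            union = agent.current_union()
            if union is not None:
                _close_union(population, agent, union, year, WIDOWHOOD)
    living = [a for a in living if a.alive(year)]

    # 2. Divorce (each union examined once, from its female or lower-id side).
    for agent in living:
        union = agent.current_union()
        if union is None:
            continue
        partner = population[union.partner_id]
        if not _owns_union(agent, partner):
            continue
        duration = year - union.start_year
        if rng.random() < rates.divorce_at(agent.race, duration):
            _close_union(population, agent, union, year, DIVORCE)

    # 3. Marriage / remarriage.
    candidates: dict[str, dict[str, list[Agent]]] = {
        race: {FEMALE: [], MALE: []} for race in RACES
    }
    for agent in living:
        if agent.married:
            continue
        last = agent.unions[-1] if agent.unions else None
        if last is not None and last.end_year == year:
            continue  # no remarriage in the year a union dissolved
        p = rates.marriage_at(agent.race, agent.age(year), agent.sex, agent.ever_married)
        if rng.random() < p:
            candidates[agent.race][agent.sex].append(agent)
    for race in RACES:
        brides = candidates[race][FEMALE]
        grooms = candidates[race][MALE]
        available = {g.id: g for g in grooms}
        for bride in brides:
            if not available:
                break
            target = bride.age(year) + rng.normal(age_gap_mean, age_gap_sd)
            target = float(np.clip(target, 18.0, 100.0))
            groom_id = min(
                available,
                key=lambda gid: (abs(available[gid].age(year) - target), gid),
            )
            _marry(population, bride, available.pop(groom_id), year)

    # 4. Fertility.
    for agent in living:
        if agent.sex != FEMALE:
            continue
        status = MARRIED if agent.married else UNMARRIED
        parity = len(agent.bio_children)
        p = rates.fertility_at(agent.race, agent.age(year), parity, status)
        if rng.random() < p:
            _give_birth(population, agent, year, rng)

    return population


def _owns_union(agent: Agent, partner: Agent) -> bool:
    if agent.sex != partner.sex:
        return agent.sex == FEMALE
    return agent.id < partner.id


def _close_union(population: Population, agent: Agent, union: UnionRecord, year: int, reason: str) -> None:
    union.end_year = year
    union.end_reason = reason
    partner = population[union.partner_id]
    for other in partner.unions:
        if other.partner_id == agent.id and other.active():
            other.end_year = year
            other.end_reason = reason
            break


def _marry(population: Population, a: Agent, b: Agent, year: int) -> None:
    for agent in (a, b):
        current = agent.current_union()
        if current is not None:
            raise ValidationError(f"agent {agent.id} already married in {year}")
    a.unions.append(UnionRecord(partner_id=b.id, start_year=year))
    b.unions.append(UnionRecord(partner_id=a.id, start_year=year))
    a.ever_married = b.ever_married = True
    # Step ties: each partner's biological children join the other's
    # stepchildren (kept disjoint from biological ties); recorded on the
    # child as a step-parent.  These ties persist after dissolution.
    for parent, spouse in ((a, b), (b, a)):
        for child_id in parent.bio_children:
            if child_id in spouse.bio_children or child_id in spouse.step_children:
                continue
            spouse.step_children.add(child_id)
            population[child_id].step_parents.add(spouse.id)


def _give_birth(population: Population, mother: Agent, year: int, rng: np.random.Generator) -> None:
    child = Agent(
        id=population.new_id(),
        sex=FEMALE if rng.random() < 0.5 else MALE,
        race=mother.race,
        birth_year=year,
    )
    population.add(child)
    mother.bio_children.add(child.id)
    child.parents.add(mother.id)
    union = mother.current_union()
    if union is not None:
        father = population[union.partner_id]
        father.bio_children.add(child.id)
        child.parents.add(father.id)


# ---------------------------------------------------------------------------
# Classification and tabulation
# ---------------------------------------------------------------------------

def classify_family_structure(agent: Agent, year: int, population: Population) -> str:
    """Six-group family-availability code for a living agent.

    Counts only children alive in ``year``; any living stepchild dominates
    biological-only classification.
    """
    if not agent.alive(year):
        raise ValidationError(f"agent {agent.id} not alive in {year}")
    n_bio, n_step = population.living_children(agent, year)
    return family_structure_code(agent.married, n_bio, n_step)


def compute_family_size(agent: Agent, year: int, population: Population) -> str:
    """Family-size category label ("0".."3", "4+") for a living agent."""
    if not agent.alive(year):
        raise ValidationError(f"agent {agent.id} not alive in {year}")
    n_bio, n_step = population.living_children(agent, year)
    return family_size_label(agent.married, n_bio, n_step)


@dataclass
class KinTabulation:
    """Population mass per (age group, sex, race, family structure, family size).

    ``data`` is a Series over the full cell grid; mass is a head count
    after :func:`tabulate_kin` and millions after :func:`scale_to_totals`.
    """

    year: int
    data: pd.Series

    def total(self) -> float:
        return float(self.data.sum())

    def shares(self, level: str) -> pd.Series:
        """Marginal shares over one index level (proportions summing to 1)."""
        margin = self.data.groupby(level=level, observed=False).sum()
        total = margin.sum()
        if total == 0:
            raise ValidationError("cannot compute shares of an empty tabulation")
        return margin / total

    def to_frame(self) -> pd.DataFrame:
        frame = self.data.rename("mass").reset_index()
        frame.insert(0, "year", self.year)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "KinTabulation":
        year = int(frame["year"].iloc[0])
        data = frame.set_index(
            ["age_group", "sex", "race", "family_structure", "family_size"]
        )["mass"]
        return cls(year=year, data=data)


def _empty_grid() -> pd.Series:
    index = pd.MultiIndex.from_product(
        [AGE_GROUPS, SEXES, RACES, FAMILY_STRUCTURES, FAMILY_SIZE_LABELS],
        names=["age_group", "sex", "race", "family_structure", "family_size"],
    )
    return pd.Series(0.0, index=index)


def tabulate_kin(
    population: Population,
    year: int,
    age_bins: tuple[int, ...] = AGE_BIN_EDGES,
) -> KinTabulation:
    """Count living agents aged 65+ into the kin-tabulation grid."""
    if tuple(age_bins) != AGE_BIN_EDGES:
        raise ConfigurationError(
            f"age bins must partition [65, 100] as {AGE_BIN_EDGES}"
        )
    data = _empty_grid()
    count = 0
    for agent in population.living(year):
        age = agent.age(year)
        if age < 65:
            continue
        if age > MAX_AGE:
            raise ValidationError(f"agent {agent.id} exceeds the age cap in {year}")
        group = AGE_GROUPS[0] if age < 75 else AGE_GROUPS[1] if age < 85 else AGE_GROUPS[2]
        structure = classify_family_structure(agent, year, population)
        size = compute_family_size(agent, year, population)
        data[(group, agent.sex, agent.race, structure, size)] += 1.0
        count += 1
    if count == 0:
        logger.warning("no living agents aged 65+ in %d; tabulation is all zero", year)
        warnings.warn(f"no living agents aged 65+ in {year}", stacklevel=2)
    return KinTabulation(year=year, data=data)


def scale_to_totals(tab: KinTabulation, total: float) -> KinTabulation:
    """Rescale cell masses so they sum to ``total`` (millions); shares unchanged."""
    if total <= 0:
        raise ValidationError("external total must be positive")
    current = tab.total()
    if current == 0:
        raise ValidationError("cannot scale an all-zero tabulation")
    return KinTabulation(year=tab.year, data=tab.data * (total / current))


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Configuration of a simulation run.

    ``initial`` is either an iterable of :class:`Agent` or a mapping
    ``(age, sex, race) -> count`` instantiated as unmarried childless
    agents at ``start_year``.  ``totals`` optionally maps output years to
    external totals (millions) for scaling.
    """

    start_year: int
    end_year: int
    rates: RateSchedule
    initial: Mapping[tuple, int] | Iterable[Agent]
    random_seed: int = 0
    output_years: tuple[int, ...] = ()
    totals: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValidationError("end_year must be >= start_year")
        for year in self.output_years:
            if not self.start_year <= year <= self.end_year:
                raise ValidationError(f"output year {year} outside simulation window")


def build_initial_population(config: SimConfig) -> Population:
    if isinstance(config.initial, Mapping):
        population = Population()
        next_id = 0
        for (age, sex, race), count in sorted(config.initial.items(), key=str):
            for _ in range(int(count)):
                population.add(
                    Agent(
                        id=next_id,
                        sex=sex,
                        race=race,
                        birth_year=config.start_year - int(age),
                    )
                )
                next_id += 1
        return population
    return Population(config.initial)


def run_simulation(config: SimConfig) -> dict[int, KinTabulation]:
    """Step the population from start to end, tabulating at output years."""
    rng = np.random.default_rng(config.random_seed)
    population = build_initial_population(config)
    output_years = config.output_years or (config.end_year,)
    results: dict[int, KinTabulation] = {}

    def collect(year: int) -> None:
        tab = tabulate_kin(population, year)
        if config.totals and year in config.totals:
            tab = scale_to_totals(tab, config.totals[year])
        results[year] = tab

    if config.start_year in output_years:
        collect(config.start_year)
    for year in range(config.start_year + 1, config.end_year + 1):
        step_year(population, config.rates, year, rng)
        if year in output_years:
            collect(year)
    return results
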