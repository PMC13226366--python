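"""One-factor-at-a-time scenario projections of care-gap counts.

The engine is a direct-standardization calculator: stratum-specific 2022
outcome probabilities are held fixed while population totals and — for
factor scenarios — one compositional margin (age structure, family
structure, or family size) evolve:

* growth-only:    ``N(year) * sum_g s_g(base) * p_g``
* factor scenario: ``N(year) * sum_g s_g(year) * p_g``

with ``N`` the 65+ total in millions, ``s_g`` stratum shares and ``p_g``
the base-year probabilities.  When probabilities are uniform across
strata every factor scenario collapses onto growth-only (the
standardization identity).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .codes import CATEGORY_OUTCOMES, OUT_NO_FAMILY_CAREGIVER, OUT_UNMET_NEED
from .exceptions import ConfigurationError, ValidationError

GROWTH_ONLY = "growth_only"
DEFAULT_FACTORS = (None, "age_group", "family_structure", "family_size")
DEFAULT_OUTCOMES = (OUT_NO_FAMILY_CAREGIVER, OUT_UNMET_NEED)

FACTOR_LABELS = {
    None: "Population growth only",
    "age_group": "& Age structure",
    "family_structure": "& Family structure",
    "family_size": "& Family size",
}


@dataclass
class ProjectionInputs:
    """Everything a scenario run needs.

    totals
        65+ population per year, in millions.
    shares
        stratifier -> DataFrame (index strata, columns years) of
        proportions; each year's column must sum to 1.
    probabilities
        stratifier -> DataFrame (index strata, columns outcomes) of
        base-year probabilities on the proportion scale.
    """

    totals: dict[int, float]
    shares: dict[str, pd.DataFrame]
    probabilities: dict[str, pd.DataFrame]
    base_year: int = 2022

    def __post_init__(self) -> None:
        for year, total in self.totals.items():
            if total <= 0:
                raise ValidationError(f"total for {year} must be positive")
        for stratifier, df in self.shares.items():
            sums = df.sum(axis=0)
            bad = sums[(sums - 1.0).abs() > 1e-6].index.tolist()
            if bad:
                raise ValidationError(
                    f"shares for {stratifier!r} do not sum to 1 in years {bad}"
                )

    def years(self) -> list[int]:
        return sorted(self.totals)

    def probability_vector(self, stratifier: str, outcome: str) -> pd.Series:
        if stratifier not in self.probabilities:
            raise ConfigurationError(f"no probabilities for stratifier {stratifier!r}")
        table = self.probabilities[stratifier]
        if outcome in table.columns:
            return table[outcome]
        if outcome == OUT_NO_FAMILY_CAREGIVER and {"none", "paid_only"}.issubset(
            table.columns
        ):
            return table["none"] + table["paid_only"]
        raise ConfigurationError(
            f"outcome {outcome!r} not available for stratifier {stratifier!r}"
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """One projection scenario.

    ``factor=None`` is growth-only; otherwise the named stratifier's
    shares evolve with the projection year while probabilities stay at
    base-year values.  ``stratifier`` overrides which probability set is
    used for growth-only (default "overall").
    """

    outcome: str
    factor: str | None = None
    stratifier: str | None = None

    @property
    def probability_stratifier(self) -> str:
        if self.factor is not None:
            return self.factor
        return self.stratifier or "overall"

    @property
    def label(self) -> str:
        return FACTOR_LABELS.get(self.factor, str(self.factor))


@dataclass
class ScenarioResult:
    """Projected counts (millions) by year plus the 2022->2040-style increase."""

    scenario: ScenarioSpec
    counts: dict[int, float] = field(default_factory=dict)

    @property
    def pct_increase(self) -> float | None:
        return pct_increase(self.counts)

    def rounded(self, ndigits: int = 1) -> dict[int, float]:
        return {y: round_half_up(c, ndigits) for y, c in self.counts.items()}


def project_counts(inputs: ProjectionInputs, scenario: ScenarioSpec, year: int) -> float:
    """Projected count (millions) for one scenario and year."""
    if year not in inputs.totals:
        raise ConfigurationError(f"no population total for year {year}")
    stratifier = scenario.probability_stratifier
    p = inputs.probability_vector(stratifier, scenario.outcome)
    if stratifier not in inputs.shares:
        raise ConfigurationError(f"no shares for stratifier {stratifier!r}")
    share_year = inputs.base_year if scenario.factor is None else year
    shares_df = inputs.shares[stratifier]
    if share_year not in shares_df.columns:
        raise ConfigurationError(
            f"no {stratifier!r} shares for year {share_year}"
        )
    s = shares_df[share_year]
    p = p.reindex(s.index)
    missing = s.index[(s > 0) & p.isna()].tolist()
    if missing:
        raise ConfigurationError(
            f"missing probability for strata {missing} "
            f"(stratifier {stratifier!r}, outcome {scenario.outcome!r})"
        )
    return float(inputs.totals[year] * (s * p).sum())


def run_scenario(
    inputs: ProjectionInputs, scenario: ScenarioSpec, years: list[int] | None = None
) -> ScenarioResult:
    years = years or inputs.years()
    counts = {year: project_counts(inputs, scenario, year) for year in years}
    return ScenarioResult(scenario=scenario, counts=counts)


def pct_increase(counts: dict[int, float]) -> float | None:
    """Percentage change from the earliest to the latest year, in percent."""
    years = sorted(counts)
    first, last = counts[years[0]], counts[years[-1]]
    if first == 0:
        warnings.warn("zero baseline count; percentage increase undefined", stacklevel=2)
        return None
    return 100.0 * (last / first - 1.0)


def run_scenario_suite(
    inputs: ProjectionInputs | dict[str, ProjectionInputs],
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES,
    factors: tuple[str | None, ...] = DEFAULT_FACTORS,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """All factor x outcome scenarios as a published-table-shaped frame.

    ``inputs`` may be a single :class:`ProjectionInputs` or a mapping of
    subgroup name -> inputs (adding a leading index level).  Columns are
    the projection years plus ``pct_increase``; values are unrounded
    millions / percentage points.
    """
    if isinstance(inputs, ProjectionInputs):
        groups = {"main": inputs}
        single = True
    else:
        groups = dict(inputs)
        single = False

    rows = []
    index = []
    for name, group_inputs in groups.items():
        group_years = years or group_inputs.years()
        for outcome in outcomes:
            for factor in factors:
                spec = ScenarioSpec(outcome=outcome, factor=factor)
                result = run_scenario(group_inputs, spec, group_years)
                row = {y: result.counts[y] for y in group_years}
                row["pct_increase"] = result.pct_increase
                rows.append(row)
                index.append((name, outcome, spec.label))
    frame = pd.DataFrame(rows)
    frame.index = pd.MultiIndex.from_tuples(
        index, names=["subgroup", "outcome", "scenario"]
    )
    if single:
        frame = frame.droplevel("subgroup")
    return frame


def expand_population(
    inputs: ProjectionInputs,
    totals: dict[int, float] | None = None,
    fraction: float | None = None,
    probabilities: dict[str, pd.DataFrame] | None = None,
) -> ProjectionInputs:
    """Inputs for an alternative population including excluded groups.

    Either explicit alternative ``totals`` are supplied, or the excluded
    group is assumed to be a fixed ``fraction`` of the base-year
    population growing in proportion to everyone else, so every year's
    total is scaled by ``1 / (1 - fraction)``.  Shares are unchanged
    (proportional-growth assumption); an expanded-sample probability set
    may replace the main one.
    """
    if (totals is None) == (fraction is None):
        raise ValidationError("supply exactly one of explicit totals or a fraction")
    if fraction is not None:
        if not 0 <= fraction < 1:
            raise ValidationError("fraction must be in [0, 1)")
        totals = {y: t / (1.0 - fraction) for y, t in inputs.totals.items()}
    return replace(
        inputs,
        totals=dict(totals),
        probabilities=dict(probabilities or inputs.probabilities),
    )


def caregiver_distribution(
    inputs: ProjectionInputs,
    factor: str | None,
    year: int,
    three_plus_value: float = 3.0,
    include_paid: bool = False,
    stratifier: str | None = None,
) -> tuple[pd.Series | None, float | None]:
    """Distribution over caregiver categories among those with care needs.

    Returns (percent distribution over {none, paid_only, fam1, fam2,
    fam3plus} summing to 100, mean caregivers per person with care needs).
    The mean uses representative counts (0, 0, 1, 2, ``three_plus_value``);
    ``include_paid`` counts the paid-only category as one caregiver, since
    whether paid helpers belong in the mean is a reporting choice.
    """
    strat = stratifier or factor or "overall"
    share_year = inputs.base_year if factor is None else year
    if strat not in inputs.shares:
        raise ConfigurationError(f"no shares for stratifier {strat!r}")
    s = inputs.shares[strat][share_year]
    masses = {}
    for outcome in CATEGORY_OUTCOMES:
        p = inputs.probability_vector(strat, outcome).reindex(s.index)
        if p.isna().any():
            raise ConfigurationError(
                f"missing category probability {outcome!r} for stratifier {strat!r}"
            )
        masses[outcome] = float((s * p).sum())
    total = sum(masses.values())
    if total <= 0:
        warnings.warn("zero care-needs mass; distribution undefined", stacklevel=2)
        return None, None
    dist = pd.Series({k: 100.0 * v / total for k, v in masses.items()})
    counts = {
        "none": 0.0,
        "paid_only": 1.0 if include_paid else 0.0,
        "fam1": 1.0,
        "fam2": 2.0,
        "fam3plus": float(three_plus_value),
    }
    mean = sum(dist[k] / 100.0 * counts[k] for k in dist.index)
    return dist, mean


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Display rounding: ties away from zero, as in published tables."""
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def plot_caregiver_distribution(
    distributions: dict[str, pd.Series], ax=None, category_labels: dict | None = None
):
    """Stacked-bar chart of caregiver-category distributions by scenario.

    ``distributions`` maps a bar label (e.g. "2022", "2040, age
    structure") to a percent distribution as returned by
    :func:`caregiver_distribution`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    labels = category_labels or {
        "none": "No caregivers",
        "paid_only": "Only paid caregivers",
        "fam1": "1 family caregiver",
        "fam2": "2 family caregivers",
        "fam3plus": "3+ family caregivers",
    }
    bars = list(distributions)
    bottom = [0.0] * len(bars)
    for outcome in CATEGORY_OUTCOMES:
        heights = [float(distributions[b][outcome]) for b in bars]
        ax.bar(bars, heights, bottom=bottom, label=labels.get(outcome, outcome))
        bottom = [b + h for b, h in zip(bottom, heights)]
    ax.set_ylabel("Percent of those with care needs")
    ax.set_ylim(0, 100)
    ax.legend(fontsize=8)
    return ax
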