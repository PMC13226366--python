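"""Model/Results interface over survey-weighted care-gap estimation.

Follows the familiar two-object pattern: :class:`CareGapModel` is built
from a classified respondent table (or directly from respondent records),
``fit()`` computes the weighted subgroup probabilities, and the returned
:class:`CareGapResults` carries the estimates, their standard errors, and
the downstream operations — margin realignment and scenario projection.

Example
-------
>>> from caregap import survey, model
>>> respondents = survey.generate_respondents(5000, seed=42)
>>> res = model.CareGapModel.from_respondents(respondents).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import projection
from .classify import classify_respondents
from .estimation import (
    DEFAULT_OUTCOMES,
    MarginSpec,
    SubgroupProbabilities,
    TransferPlan,
    realign_distribution,
    weighted_outcome_stats,
)
from .exceptions import ConfigurationError
from .records import SurveyRespondent


class CareGapModel:
    """Weighted subgroup-probability model of care-gap outcomes.

    Parameters
    ----------
    data:
        Classified respondent table with one row per respondent: the
        stratifier column, a positive ``weight`` column, and the outcome
        indicator columns produced by
        :func:`caregap.classify.classify_respondents`.
    stratifier:
        Column defining the estimation strata (default family structure).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        stratifier: str = "family_structure",
        weight_col: str = "weight",
        outcomes: tuple[str, ...] = DEFAULT_OUTCOMES,
    ):
        if stratifier not in data.columns:
            raise ConfigurationError(f"stratifier column {stratifier!r} not in data")
        self.data = data
        self.stratifier = stratifier
        self.weight_col = weight_col
        self.outcomes = tuple(outcomes)

    @classmethod
    def from_respondents(
        cls,
        respondents: list[SurveyRespondent],
        stratifier: str = "family_structure",
        outcomes: tuple[str, ...] = DEFAULT_OUTCOMES,
    ) -> "CareGapModel":
        """Classify raw survey records and build the model."""
        return cls(classify_respondents(respondents), stratifier=stratifier, outcomes=outcomes)

    def fit(self) -> "CareGapResults":
        probs, ses, nobs, sumw = weighted_outcome_stats(
            self.data, self.stratifier, self.outcomes, self.weight_col
        )
        return CareGapResults(
            model=self, params=probs, bse=ses, nobs=nobs, sum_weights=sumw
        )

    def margins(self) -> MarginSpec:
        """Weighted stratum shares observed in the data."""
        w = self.data.groupby(self.stratifier, sort=True, observed=True)[
            self.weight_col
        ].sum()
        return MarginSpec(self.stratifier, w / w.sum())


@dataclass
class CareGapResults:
    """Fitted subgroup probabilities with uncertainty and projections.

    Attributes
    ----------
    params : DataFrame
        Per-stratum outcome probabilities (proportion scale).
    bse : DataFrame
        Standard errors (with-replacement weighted-proportion formula).
    nobs, sum_weights : Series
        Respondents and total weight per stratum.
    """

    model: CareGapModel
    params: pd.DataFrame
    bse: pd.DataFrame
    nobs: pd.Series
    sum_weights: pd.Series

    @property
    def stratifier(self) -> str:
        return self.model.stratifier

    def subgroup_probabilities(self) -> SubgroupProbabilities:
        return SubgroupProbabilities(self.stratifier, self.params)

    def conf_int(self, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
        """Normal-approximation confidence bounds per outcome."""
        from statistics import NormalDist

        z = NormalDist().inv_cdf(1 - alpha / 2)
        return {
            "lower": (self.params - z * self.bse).clip(lower=0.0),
            "upper": (self.params + z * self.bse).clip(upper=1.0),
        }

    def realign(
        self,
        target: MarginSpec,
        plan: TransferPlan | None = None,
        source: MarginSpec | None = None,
    ) -> SubgroupProbabilities:
        """Realign the fitted probabilities to external margins.

        ``source`` defaults to the weighted margins observed in the data.
        """
        source = source or self.model.margins()
        return realign_distribution(source, self.subgroup_probabilities(), target, plan)

    def projection_inputs(
        self,
        totals: dict[int, float],
        shares: pd.DataFrame,
        probabilities: SubgroupProbabilities | None = None,
        base_year: int = 2022,
    ) -> projection.ProjectionInputs:
        """Assemble projection inputs from fitted (or realigned) probabilities.

        ``shares`` is a stratum x year frame for this results object's
        stratifier; an "overall" probability row is derived from the
        base-year share-weighted average so growth-only scenarios work.
        """
        probs = (probabilities or self.subgroup_probabilities()).table
        base = shares[base_year]
        overall = (probs.mul(base, axis=0)).sum(axis=0) / base.sum()
        return projection.ProjectionInputs(
            totals=dict(totals),
            shares={
                self.stratifier: shares,
                "overall": pd.DataFrame(
                    {year: [1.0] for year in shares.columns}, index=["overall"]
                ),
            },
            probabilities={
                self.stratifier: probs,
                "overall": overall.to_frame().T.set_axis(["overall"], axis=0),
            },
            base_year=base_year,
        )

    def project(
        self,
        totals: dict[int, float],
        shares: pd.DataFrame,
        outcomes: tuple[str, ...] = projection.DEFAULT_OUTCOMES,
        probabilities: SubgroupProbabilities | None = None,
        base_year: int = 2022,
    ) -> pd.DataFrame:
        """Growth-only plus this-stratifier scenario projections."""
        inputs = self.projection_inputs(totals, shares, probabilities, base_year)
        return projection.run_scenario_suite(
            inputs, outcomes=outcomes, factors=(None, self.stratifier)
        )

    def summary(self) -> str:
        """Human-readable estimation summary."""
        lines = []
        title = "Care-gap subgroup probability estimates"
        lines.append(title)
        lines.append("=" * 72)
        lines.append(f"Stratifier:        {self.stratifier}")
        lines.append(f"No. respondents:   {int(self.nobs.sum())}")
        lines.append(f"Strata:            {len(self.params.index)}")
        lines.append(f"Weighted N:        {self.sum_weights.sum():.1f}")
        lines.append("-" * 72)
        show = [
            c
            for c in (
                "no_family_caregiver",
                "none",
                "paid_only",
                "fam1",
                "fam2",
                "fam3plus",
                "unmet_need",
            )
            if c in self.params.columns
        ]
        table = (100 * self.params[show]).round(1).astype(str)
        se = (100 * self.bse[show]).round(1)
        for col in show:
            table[col] = table[col] + " (" + se[col].astype(str) + ")"
        table.insert(0, "n", self.nobs)
        lines.append(table.to_string())
        lines.append("-" * 72)
        lines.append("Percent scale; standard errors in parentheses.")
        return "\n".join(lines)
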