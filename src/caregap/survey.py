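"""Synthetic survey generator.

Emulates a weighted cross-sectional interview of community-dwelling
adults 65+ (in the style of a national aging-and-care panel): each
respondent carries a design weight, demographic strata, child counts, and
activity-level help records, fabricated so that the classifiers in
:mod:`caregap.classify` recover configurable per-stratum outcome
probabilities in expectation.

The default parameters transcribe the packaged 2022 benchmark
probabilities (share with no caregivers, only paid caregivers, and unmet
need per stratum).  The benchmark prints only those marginals, so the
remaining care-needs mass and its split across 1/2/3+ family caregivers
are explicit simulation parameters with documented defaults, not claims
about the source survey.

One coherence constraint is unavoidable: under the standard care-needs
definition a respondent with zero helpers can only have care needs
through an unmet need, so within the "no caregivers" category unmet need
has probability 1.  Where a stratum's target unmet-need share is below
its no-caregivers share the generator gets as close as the classifier
allows; :meth:`OutcomeParams.effective_probabilities` reports the rates
the generator actually attains in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codes import NO_CARE_NEEDS, CAREGIVER_CATEGORIES
from .exceptions import ConfigurationError, ValidationError
from .records import (
    ActivityRecord,
    Helper,
    N_CONSEQUENCE_FLAGS,
    REASON_HEALTH,
    REASON_OTHER,
    SurveyRespondent,
)

_CATEGORY_COLUMNS = ["no_care_needs", "none", "paid_only", "fam1", "fam2", "fam3plus"]

#: Default share of care-needs respondents with an unmet need, applied to
#: every stratum to back out total care-needs prevalence from the printed
#: unmet-need share (overall, unmet needs affect just over half of those
#: with care needs).
DEFAULT_UNMET_GIVEN_NEEDS = 0.52

#: Default split of the residual care-needs mass across 1/2/3+ family
#: caregivers (stylized from the published category distribution among
#: those with care needs).
DEFAULT_FAMILY_SPLIT = (0.563, 0.243, 0.194)

#: Share of no-care-needs respondents given an unassisted difficulty
#: (drives the broad-definition sensitivity margin).
DEFAULT_P_DIFFICULTY_NO_NEEDS = 0.306

#: Share of no-care-needs respondents given household help for a
#: non-health reason (which the classifiers must ignore).
DEFAULT_P_NONHEALTH_HELP = 0.10


@dataclass
class OutcomeParams:
    """Per-stratum generating probabilities.

    ``table`` is indexed by stratum with columns ``no_care_needs, none,
    paid_only, fam1, fam2, fam3plus`` (summing to 1 per row) and
    ``unmet_target`` — the unconditional unmet-need share the stratum
    should exhibit.
    """

    stratifier: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CATEGORY_COLUMNS + ["unmet_target"] if c not in self.table.columns]
        if missing:
            raise ValidationError(f"OutcomeParams table missing columns {missing}")
        values = self.table[_CATEGORY_COLUMNS + ["unmet_target"]].to_numpy()
        if (values < -1e-12).any() or (values > 1 + 1e-12).any():
            raise ValidationError("OutcomeParams probabilities outside [0, 1]")
        sums = self.table[_CATEGORY_COLUMNS].sum(axis=1)
        bad = sums[(sums - 1.0).abs() > 1e-9].index.tolist()
        if bad:
            raise ValidationError(f"category probabilities do not sum to 1 for strata {bad}")

    @property
    def strata(self) -> list:
        return list(self.table.index)

    def care_needs(self) -> pd.Series:
        return 1.0 - self.table["no_care_needs"]

    def unmet_given_helped(self) -> pd.Series:
        """P(unmet | care needs with at least one helper), solved from the
        unconditional target with category "none" forced to unmet=1 and
        clipped into [0, 1] where the target is infeasible."""
        p_none = self.table["none"]
        helped = self.care_needs() - p_none
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (self.table["unmet_target"] - p_none) / helped
        q = q.where(helped > 0, 0.0)
        return q.clip(0.0, 1.0)

    def effective_probabilities(self) -> pd.DataFrame:
        """Rates the classifier recovers in expectation.

        Caregiver categories are attained exactly; effective unmet need is
        ``p(none) + p(helped) * q`` with ``q`` the clipped conditional,
        which equals the target whenever the target is feasible.
        """
        q = self.unmet_given_helped()
        helped = self.care_needs() - self.table["none"]
        eff = self.table[_CATEGORY_COLUMNS].copy()
        eff["no_family_caregiver"] = eff["none"] + eff["paid_only"]
        eff["unmet_need"] = self.table["none"] + helped * q
        eff["care_needs"] = self.care_needs()
        return eff


def default_params(
    stratifier: str = "family_structure",
    unmet_given_needs: float = DEFAULT_UNMET_GIVEN_NEEDS,
    family_split: tuple[float, float, float] = DEFAULT_FAMILY_SPLIT,
) -> OutcomeParams:
    """Generating parameters transcribed from the packaged 2022 benchmark.

    For each stratum the benchmark fixes p(no caregivers), p(only paid)
    and the unconditional unmet-need share; total care-needs prevalence is
    backed out as ``unmet / unmet_given_needs`` and the residual mass is
    split across 1/2/3+ family caregivers by ``family_split``.
    """
    from .fixtures import benchmark_probabilities  # local import; fixtures imports estimation

    split = np.asarray(family_split, dtype=float)
    if (split < 0).any() or abs(split.sum() - 1.0) > 1e-9:
        raise ValidationError("family_split must be a distribution over 1/2/3+")
    bench = benchmark_probabilities(stratifier).table
    rows = {}
    for stratum, row in bench.iterrows():
        p_none, p_paid, p_unmet = row["none"], row["paid_only"], row["unmet_need"]
        p_care = p_unmet / unmet_given_needs
        residual = p_care - p_none - p_paid
        if residual < 0:
            raise ValidationError(
                f"stratum {stratum!r}: implied care-needs prevalence {p_care:.3f} "
                "below the no-family-caregiver share; raise unmet_given_needs"
            )
        rows[stratum] = {
            "no_care_needs": 1.0 - p_care,
            "none": p_none,
            "paid_only": p_paid,
            "fam1": residual * split[0],
            "fam2": residual * split[1],
            "fam3plus": residual * split[2],
            "unmet_target": p_unmet,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return OutcomeParams(stratifier, table)


def default_margins() -> dict[str, dict]:
    """Base-year demographic margins from the packaged benchmark."""
    from .fixtures import benchmark_shares

    out = {}
    for stratifier in ("age_group", "sex", "race", "family_structure"):
        shares = benchmark_shares(stratifier)[2022]
        out[stratifier] = shares.to_dict()
    return out


# Activities/helpers used to fabricate minimal consistent records.
_FAMILY_ACTIVITIES = ("bathing", "dressing", "getting around inside")
_FAMILY_RELATIONSHIPS = ("daughter", "son", "spouse")


def generate_respondents(
    n: int,
    margins: dict[str, dict] | None = None,
    params: OutcomeParams | None = None,
    seed: int | np.random.Generator = 0,
    weight_sigma: float = 0.5,
    p_difficulty_no_needs: float = DEFAULT_P_DIFFICULTY_NO_NEEDS,
    p_nonhealth_help: float = DEFAULT_P_NONHEALTH_HELP,
) -> list[SurveyRespondent]:
    """Draw ``n`` synthetic respondents.

    Demographic strata are drawn independently from ``margins`` (default:
    the benchmark's 2022 distributions), weights from a lognormal scaled
    to mean 1, and outcomes from ``params`` for the respondent's stratum
    on ``params.stratifier``.  Records are minimal but classifier-exact:
    one helped activity per family caregiver, a single paid helper for
    paid-only, at least one adverse-consequence flag for unmet need.
    Fully reproducible given the seed.
    """
    if n < 0:
        raise ValidationError("n must be nonnegative")
    params = params or default_params()
    margins = margins or default_margins()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    for stratifier, shares in margins.items():
        values = np.asarray(list(shares.values()), dtype=float)
        if (values < 0).any() or abs(values.sum() - 1.0) > 1e-6:
            raise ValidationError(
                f"margins for {stratifier!r} are not a proper distribution"
            )
    if n == 0:
        return []

    draws = {}
    for stratifier in ("age_group", "sex", "race", "family_structure", "family_size"):
        if stratifier in margins:
            labels = list(margins[stratifier])
            probs = np.asarray(list(margins[stratifier].values()), dtype=float)
            probs = probs / probs.sum()
            draws[stratifier] = rng.choice(len(labels), size=n, p=probs)
            draws[stratifier + "_labels"] = labels
    if "family_structure" not in draws and "family_size" not in draws:
        raise ConfigurationError(
            "margins must include family_structure or family_size"
        )

    weights = rng.lognormal(mean=0.0, sigma=weight_sigma, size=n)
    weights = weights / np.exp(weight_sigma**2 / 2.0)  # theoretical mean -> 1

    # Family composition coherent with the drawn structure/size stratum.
    married = np.zeros(n, dtype=bool)
    n_bio = np.zeros(n, dtype=int)
    n_step = np.zeros(n, dtype=int)
    if "family_structure" in draws:
        codes = [draws["family_structure_labels"][i] for i in draws["family_structure"]]
        extra_bio = rng.poisson(1.2, size=n)
        extra_step = rng.poisson(0.8, size=n)
        for i, code in enumerate(codes):
            married[i] = code.startswith("M")
            if code.endswith("B"):
                n_bio[i] = 1 + extra_bio[i]
            elif code.endswith("S"):
                n_step[i] = 1 + extra_step[i]
                n_bio[i] = extra_bio[i]
    else:
        sizes = [int(str(draws["family_size_labels"][i]).rstrip("+")) for i in draws["family_size"]]
        married_draw = rng.random(n) < 0.5
        extra = rng.poisson(1.0, size=n)
        for i, size in enumerate(sizes):
            if size >= 4:
                size = 4 + extra[i]
            married[i] = bool(married_draw[i]) and size >= 1
            n_bio[i] = size - int(married[i])

    # Outcome category per respondent, stratified on params.stratifier.
    strata = _respondent_strata(params.stratifier, draws, married, n_bio, n_step, n)
    stratum_index = {s: k for k, s in enumerate(params.strata)}
    cum = params.table[_CATEGORY_COLUMNS].to_numpy().cumsum(axis=1)
    q_helped = params.unmet_given_helped()

    try:
        rows = np.asarray([stratum_index[s] for s in strata])
    except KeyError as err:
        raise ConfigurationError(
            f"no outcome parameters for stratum {err.args[0]!r} "
            f"(stratifier {params.stratifier!r})"
        ) from None
    u = rng.random(n)
    category_idx = (u[:, None] > cum[rows]).sum(axis=1)
    category_idx = np.minimum(category_idx, len(_CATEGORY_COLUMNS) - 1)

    unmet_u = rng.random(n)
    difficulty_u = rng.random(n)
    nonhealth_u = rng.random(n)

    respondents = []
    categories = [NO_CARE_NEEDS] + list(CAREGIVER_CATEGORIES)
    for i in range(n):
        category = categories[category_idx[i]]
        stratum = strata[i]
        activities: list[ActivityRecord] = []
        consequences = [False] * N_CONSEQUENCE_FLAGS

        if category == NO_CARE_NEEDS:
            if difficulty_u[i] < p_difficulty_no_needs:
                activities.append(ActivityRecord("bathing", difficulty=True))
            if nonhealth_u[i] < p_nonhealth_help:
                activities.append(
                    ActivityRecord(
                        "shopping",
                        helpers=[Helper("daughter", paid=False, helper_id="fam-1")],
                        reason=REASON_OTHER,
                    )
                )
        elif category == "none":
            # Zero helpers: care needs can only come from an unmet need.
            activities.append(ActivityRecord("bathing", difficulty=True))
            consequences[0] = True
        elif category == "paid-only":
            activities.append(
                ActivityRecord(
                    "bathing",
                    difficulty=True,
                    helpers=[Helper("aide", paid=True, helper_id="paid-1")],
                )
            )
            if unmet_u[i] < q_helped[stratum]:
                consequences[0] = True
        else:
            k = {"1": 1, "2": 2, "3+": 3}[category]
            for j in range(k):
                activities.append(
                    ActivityRecord(
                        _FAMILY_ACTIVITIES[j],
                        difficulty=True,
                        helpers=[
                            Helper(
                                _FAMILY_RELATIONSHIPS[j],
                                paid=False,
                                helper_id=f"fam-{j + 1}",
                            )
                        ],
                    )
                )
            if unmet_u[i] < q_helped[stratum]:
                consequences[0] = True

        respondents.append(
            SurveyRespondent(
                id=i,
                weight=float(weights[i]),
                age_group=_label(draws, "age_group", i, "65-74"),
                sex=_label(draws, "sex", i, "female"),
                race=_label(draws, "race", i, "White"),
                married=bool(married[i]),
                n_bio=int(n_bio[i]),
                n_step=int(n_step[i]),
                activities=activities,
                consequences=consequences,
            )
        )
    return respondents


def _respondent_strata(stratifier, draws, married, n_bio, n_step, n):
    from .codes import family_size_label, family_structure_code

    if stratifier == "overall":
        return ["overall"] * n
    if stratifier == "family_structure":
        return [family_structure_code(married[i], n_bio[i], n_step[i]) for i in range(n)]
    if stratifier == "family_size":
        return [family_size_label(married[i], n_bio[i], n_step[i]) for i in range(n)]
    if stratifier in draws:
        labels = draws[stratifier + "_labels"]
        return [labels[k] for k in draws[stratifier]]
    raise ConfigurationError(
        f"margins do not cover params stratifier {stratifier!r}"
    )


def _label(draws, stratifier, i, default):
    if stratifier in draws:
        return draws[stratifier + "_labels"][draws[stratifier][i]]
    return default
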