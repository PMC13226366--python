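"""Care-gap outcome classification.

Derives, from activity-level records, the outcome measures used throughout
the package:

* **care needs** — received help with a self-care, mobility, or household
  activity (household help counting only when given for health or
  functioning reasons) OR reported an unmet need for help.  A *broad*
  sensitivity definition additionally counts unassisted difficulty.
* **caregiver-network category** — the number (0 through 3 or more) of
  distinct relatives and other unpaid caregivers ("family caregivers",
  broadly defined) assisting for health/functioning reasons, with an extra
  category for reliance on only paid non-family caregivers.
* **unmet need** — any adverse-consequence flag (e.g. having to stay in
  bed, going without bathing) attributed to the absence of help.

Helpers who are paid are never family caregivers, whatever their
relationship; distinct helpers are identified by their (helper id, paid)
identity tokens.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .codes import (
    CG_NONE,
    CG_ONE,
    CG_PAID_ONLY,
    CG_THREE_PLUS,
    CG_TWO,
    NO_CARE_NEEDS,
)
from .exceptions import ValidationError
from .records import HOUSEHOLD, REASON_HEALTH, SurveyRespondent


@dataclass(frozen=True)
class CareProfile:
    """Classified outcomes for one respondent."""

    care_needs: bool
    caregiver_category: str  # "no care needs", "none", "paid-only", "1", "2", "3+"
    unmet_need: bool
    care_needs_broad: bool

    def __post_init__(self) -> None:
        if (self.caregiver_category == NO_CARE_NEEDS) != (not self.care_needs):
            raise ValidationError("caregiver_category inconsistent with care_needs")
        if self.unmet_need and not self.care_needs:
            raise ValidationError("unmet_need implies care_needs")
        if self.care_needs and not self.care_needs_broad:
            raise ValidationError("care_needs implies care_needs_broad")

    @property
    def no_family_caregiver(self) -> bool:
        """Care needs with neither family nor unpaid caregiver (none or paid-only)."""
        return self.caregiver_category in (CG_NONE, CG_PAID_ONLY)


def _counted_helpers(respondent: SurveyRespondent):
    """Yield helpers on activities that count toward care measures.

    Household-activity help counts only when the recorded reason is
    health/functioning; self-care and mobility help always counts.
    """
    for act in respondent.activities:
        if act.domain == HOUSEHOLD and act.reason != REASON_HEALTH:
            continue
        yield from act.helpers


def classify_caregiver_network(respondent: SurveyRespondent) -> str:
    """Caregiver-network category among {none, paid-only, 1, 2, 3+}.

    Distinct unpaid helpers across all counted activities, capped at "3 or
    more"; with zero unpaid helpers, any paid helper yields "paid-only",
    otherwise "none".  The paid-only check applies whenever the unpaid
    count is zero, regardless of how many paid helpers there are.
    """
    unpaid: set = set()
    any_paid = False
    for h in _counted_helpers(respondent):
        if h.paid:
            any_paid = True
        else:
            unpaid.add(h.identity)
    n = len(unpaid)
    if n == 0:
        return CG_PAID_ONLY if any_paid else CG_NONE
    if n == 1:
        return CG_ONE
    if n == 2:
        return CG_TWO
    return CG_THREE_PLUS


def classify_unmet_need(respondent: SurveyRespondent) -> bool:
    """True iff any adverse-consequence flag is set."""
    return any(respondent.consequences)


def classify_care_needs(respondent: SurveyRespondent, definition: str = "standard") -> bool:
    """Care-needs indicator under the standard or broad definition."""
    if definition not in ("standard", "broad"):
        raise ValidationError(f"unknown care-needs definition {definition!r}")
    received_help = any(True for _ in _counted_helpers(respondent))
    standard = received_help or classify_unmet_need(respondent)
    if definition == "standard":
        return standard
    any_difficulty = any(a.difficulty for a in respondent.activities)
    return standard or any_difficulty


def classify(respondent: SurveyRespondent) -> CareProfile:
    """Full outcome profile for one respondent.

    Respondents with unassisted difficulty but no standard-definition care
    need are assigned caregiver category "no care needs" (they enter the
    network categories only under the broad definition, as "none").
    """
    care_needs = classify_care_needs(respondent, "standard")
    broad = classify_care_needs(respondent, "broad")
    unmet = classify_unmet_need(respondent) if care_needs else False
    category = classify_caregiver_network(respondent) if care_needs else NO_CARE_NEEDS
    return CareProfile(
        care_needs=care_needs,
        caregiver_category=category,
        unmet_need=unmet,
        care_needs_broad=broad,
    )


def classify_respondents(respondents: list[SurveyRespondent]) -> pd.DataFrame:
    """Respondent-level outcome table (one row per respondent).

    Columns cover the demographic stratifiers, the survey weight and the
    classified outcomes; this is the input expected by
    :class:`caregap.model.CareGapModel`.
    """
    rows = []
    for r in respondents:
        profile = classify(r)
        rows.append(
            {
                "id": r.id,
                "weight": r.weight,
                "overall": "overall",
                "age_group": r.age_group,
                "sex": r.sex,
                "race": r.race,
                "family_structure": r.family_structure,
                "family_size": r.family_size_label,
                "care_needs": profile.care_needs,
                "care_needs_broad": profile.care_needs_broad,
                "caregiver_category": profile.caregiver_category,
                "no_family_caregiver": profile.no_family_caregiver,
                "unmet_need": profile.unmet_need,
            }
        )
    cols = ["id", "weight", "overall", "age_group", "sex", "race",
            "family_structure", "family_size", "care_needs", "care_needs_broad",
            "caregiver_category", "no_family_caregiver", "unmet_need"]
    return pd.DataFrame(rows, columns=cols)
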