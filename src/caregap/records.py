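"""Survey record containers.

A :class:`SurveyRespondent` mirrors the activity-level structure of a
disability-and-care interview: eleven activities spanning self-care,
mobility and household domains, each with a difficulty flag, a helper
roster (relationship + paid flag), and — for household activities only —
the reason help was received.  Adverse-consequence flags (one per probed
domain) capture unmet care needs.

Respondent tables round-trip through three tidy CSVs (respondents,
activities, helpers) so classified outcomes can be recomputed from disk.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from .codes import family_size_category, family_size_label, family_structure_code
from .exceptions import ValidationError

SELF_CARE = "self-care"
MOBILITY = "mobility"
HOUSEHOLD = "household"

#: The eleven probed activities and their fixed domain assignment.
ACTIVITY_DOMAINS: dict[str, str] = {
    "eating": SELF_CARE,
    "bathing": SELF_CARE,
    "toileting": SELF_CARE,
    "dressing": SELF_CARE,
    "getting around inside": MOBILITY,
    "getting out of bed": MOBILITY,
    "laundry": HOUSEHOLD,
    "meals": HOUSEHOLD,
    "shopping": HOUSEHOLD,
    "bills": HOUSEHOLD,
    "medications": HOUSEHOLD,
}
ACTIVITIES = tuple(ACTIVITY_DOMAINS)

REASON_HEALTH = "health/functioning"
REASON_OTHER = "other"

#: Number of adverse-consequence flags probed per respondent.
N_CONSEQUENCE_FLAGS = 5


@dataclass(frozen=True)
class Helper:
    """One helper on one activity.

    ``helper_id`` identifies the person across activities so distinct
    caregivers can be counted; it defaults to the relationship label.
    """

    relationship: str
    paid: bool
    helper_id: str | None = None

    @property
    def identity(self) -> tuple[str, bool]:
        return (self.helper_id or self.relationship, self.paid)


@dataclass
class ActivityRecord:
    activity: str
    difficulty: bool = False
    helpers: list[Helper] = field(default_factory=list)
    reason: str | None = None  # household activities only

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITY_DOMAINS:
            raise ValidationError(f"unknown activity {self.activity!r}")
        if self.reason is not None and self.domain != HOUSEHOLD:
            raise ValidationError(
                f"reason recorded for non-household activity {self.activity!r}"
            )
        if self.reason is not None and self.reason not in (REASON_HEALTH, REASON_OTHER):
            raise ValidationError(f"unknown reason {self.reason!r}")

    @property
    def domain(self) -> str:
        return ACTIVITY_DOMAINS[self.activity]


@dataclass
class SurveyRespondent:
    id: int
    weight: float
    age_group: str
    sex: str
    race: str
    married: bool
    n_bio: int
    n_step: int
    activities: list[ActivityRecord] = field(default_factory=list)
    consequences: list[bool] = field(default_factory=lambda: [False] * N_CONSEQUENCE_FLAGS)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValidationError(f"respondent {self.id}: weight must be > 0")
        if self.n_bio < 0 or self.n_step < 0:
            raise ValidationError(f"respondent {self.id}: negative child count")

    @property
    def family_structure(self) -> str:
        return family_structure_code(self.married, self.n_bio, self.n_step)

    @property
    def family_size(self) -> int:
        return family_size_category(self.married, self.n_bio, self.n_step)

    @property
    def family_size_label(self) -> str:
        return family_size_label(self.married, self.n_bio, self.n_step)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def respondents_to_frames(
    respondents: list[SurveyRespondent],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Flatten respondents into (respondent, activity, helper) tables."""
    resp_rows, act_rows, helper_rows = [], [], []
    for r in respondents:
        resp_rows.append(
            {
                "id": r.id,
                "weight": r.weight,
                "age_group": r.age_group,
                "sex": r.sex,
                "race": r.race,
                "married": r.married,
                "n_bio": r.n_bio,
                "n_step": r.n_step,
                "consequences": ";".join("1" if c else "0" for c in r.consequences),
            }
        )
        for a in r.activities:
            act_rows.append(
                {
                    "respondent_id": r.id,
                    "activity": a.activity,
                    "difficulty": a.difficulty,
                    "reason": a.reason if a.reason is not None else "",
                }
            )
            for h in a.helpers:
                helper_rows.append(
                    {
                        "respondent_id": r.id,
                        "activity": a.activity,
                        "relationship": h.relationship,
                        "paid": h.paid,
                        "helper_id": h.helper_id or "",
                    }
                )
    resp_cols = ["id", "weight", "age_group", "sex", "race", "married",
                 "n_bio", "n_step", "consequences"]
    act_cols = ["respondent_id", "activity", "difficulty", "reason"]
    helper_cols = ["respondent_id", "activity", "relationship", "paid", "helper_id"]
    return (
        pd.DataFrame(resp_rows, columns=resp_cols),
        pd.DataFrame(act_rows, columns=act_cols),
        pd.DataFrame(helper_rows, columns=helper_cols),
    )


def respondents_from_frames(
    resp: pd.DataFrame, acts: pd.DataFrame, helpers: pd.DataFrame
) -> list[SurveyRespondent]:
    """Inverse of :func:`respondents_to_frames`."""
    helper_map: dict[tuple[int, str], list[Helper]] = {}
    for row in helpers.itertuples(index=False):
        key = (int(row.respondent_id), row.activity)
        hid = row.helper_id if isinstance(row.helper_id, str) and row.helper_id else None
        helper_map.setdefault(key, []).append(
            Helper(relationship=row.relationship, paid=_to_bool(row.paid), helper_id=hid)
        )
    act_map: dict[int, list[ActivityRecord]] = {}
    for row in acts.itertuples(index=False):
        rid = int(row.respondent_id)
        reason = row.reason if isinstance(row.reason, str) and row.reason else None
        act_map.setdefault(rid, []).append(
            ActivityRecord(
                activity=row.activity,
                difficulty=_to_bool(row.difficulty),
                helpers=helper_map.get((rid, row.activity), []),
                reason=reason,
            )
        )
    out = []
    for row in resp.itertuples(index=False):
        rid = int(row.id)
        cons = [c == "1" for c in str(row.consequences).split(";")] if str(
            row.consequences
        ) else []
        out.append(
            SurveyRespondent(
                id=rid,
                weight=float(row.weight),
                age_group=row.age_group,
                sex=row.sex,
                race=row.race,
                married=_to_bool(row.married),
                n_bio=int(row.n_bio),
                n_step=int(row.n_step),
                activities=act_map.get(rid, []),
                consequences=cons,
            )
        )
    return out


def write_respondents(respondents: list[SurveyRespondent], directory: str) -> dict[str, str]:
    """Write the three-table CSV representation into ``directory``."""
    os.makedirs(directory, exist_ok=True)
    resp, acts, helpers = respondents_to_frames(respondents)
    paths = {
        "respondents": os.path.join(directory, "respondents.csv"),
        "activities": os.path.join(directory, "activities.csv"),
        "helpers": os.path.join(directory, "helpers.csv"),
    }
    resp.to_csv(paths["respondents"], index=False)
    acts.to_csv(paths["activities"], index=False)
    helpers.to_csv(paths["helpers"], index=False)
    return paths


def read_respondents(directory: str) -> list[SurveyRespondent]:
    resp = pd.read_csv(os.path.join(directory, "respondents.csv"))
    acts = pd.read_csv(os.path.join(directory, "activities.csv"), keep_default_na=False)
    helpers = pd.read_csv(os.path.join(directory, "helpers.csv"), keep_default_na=False)
    return respondents_from_frames(resp, acts, helpers)


def _to_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("true", "1", "yes")
    return bool(x)
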