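"""Category codes shared across the package.

Family availability uses six mutually exclusive groups crossing marital
status with children: unmarried with no children (``U0``), with biological
children only (``UB``), with any stepchildren (``US``), and the married
analogues (``M0``, ``MB``, ``MS``).  "Any stepchildren" dominates: an older
adult with both biological and stepchildren is classified ``US``/``MS``.

Family size counts spouse plus biological plus stepchildren, capped at 4
("4 or more").  Age groups follow the 65-74 / 75-84 / 85+ convention with
a hard cap at age 100.
"""

from __future__ import annotations

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

WHITE = "White"
BLACK = "Black"
RACES = (WHITE, BLACK)

AGE_GROUPS = ("65-74", "75-84", "85+")
#: Half-open bin edges for the three age groups; the last bin is closed at 100.
AGE_BIN_EDGES = (65, 75, 85, 101)
MAX_AGE = 100

FAMILY_STRUCTURES = ("U0", "UB", "US", "M0", "MB", "MS")
MARRIED_STRUCTURES = frozenset({"M0", "MB", "MS"})

#: Family-size categories; 4 denotes "4 or more".
FAMILY_SIZES = (0, 1, 2, 3, 4)
FAMILY_SIZE_LABELS = ("0", "1", "2", "3", "4+")

# Caregiver-network categories among the full population.
NO_CARE_NEEDS = "no care needs"
CG_NONE = "none"
CG_PAID_ONLY = "paid-only"
CG_ONE = "1"
CG_TWO = "2"
CG_THREE_PLUS = "3+"
CAREGIVER_CATEGORIES = (CG_NONE, CG_PAID_ONLY, CG_ONE, CG_TWO, CG_THREE_PLUS)

# Outcome column names used by probability tables and the projection engine.
OUT_NONE = "none"
OUT_PAID_ONLY = "paid_only"
OUT_FAM1 = "fam1"
OUT_FAM2 = "fam2"
OUT_FAM3PLUS = "fam3plus"
OUT_NO_FAMILY_CAREGIVER = "no_family_caregiver"  # none + paid-only
OUT_UNMET_NEED = "unmet_need"
OUT_CARE_NEEDS = "care_needs"
OUT_NO_CARE_NEEDS = "no_care_needs"

CATEGORY_OUTCOMES = (OUT_NONE, OUT_PAID_ONLY, OUT_FAM1, OUT_FAM2, OUT_FAM3PLUS)

#: Map caregiver-network category label -> outcome column.
CATEGORY_TO_OUTCOME = {
    CG_NONE: OUT_NONE,
    CG_PAID_ONLY: OUT_PAID_ONLY,
    CG_ONE: OUT_FAM1,
    CG_TWO: OUT_FAM2,
    CG_THREE_PLUS: OUT_FAM3PLUS,
}

STRATIFIERS = ("overall", "age_group", "sex", "race", "family_structure", "family_size")


def age_group_of(age: int) -> str | None:
    """Return the 65+ age-group label for ``age``, or None below 65."""
    if age < 65:
        return None
    if age < 75:
        return "65-74"
    if age < 85:
        return "75-84"
    return "85+"


def family_structure_code(married: bool, n_bio: int, n_step: int) -> str:
    """Six-group family-availability code; any stepchildren dominate."""
    if n_step > 0:
        kids = "S"
    elif n_bio > 0:
        kids = "B"
    else:
        kids = "0"
    return ("M" if married else "U") + kids


def family_size_category(married: bool, n_bio: int, n_step: int) -> int:
    """Spouse + biological + stepchildren count, capped at 4 ("4 or more")."""
    return min(int(married) + n_bio + n_step, 4)


def family_size_label(married: bool, n_bio: int, n_step: int) -> str:
    """Family-size category as the printed label ("0".."3", "4+")."""
    return FAMILY_SIZE_LABELS[family_size_category(married, n_bio, n_step)]
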