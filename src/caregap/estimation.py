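"""Survey-weighted subgroup estimation and margin realignment.

Probabilities are ratio estimates: for stratum *g* and outcome *y*,
``p_g = sum(w_i * y_i, i in g) / sum(w_i, i in g)``.  They are invariant
to rescaling all weights and reduce to unweighted proportions under
constant weights.

Realignment adjusts a stratifier's margins toward an external (simulated)
distribution by moving mass between declared donor -> recipient pairs.
Transferred mass retains the outcome distribution of its origin stratum,
so a recipient's probabilities become the mass-weighted mixture of
incumbent and transferred mass; donors keep their probabilities.  The
margin-weighted expected outcome mass is conserved exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .codes import (
    CATEGORY_OUTCOMES,
    CATEGORY_TO_OUTCOME,
    FAMILY_SIZE_LABELS,
    FAMILY_STRUCTURES,
    OUT_NO_CARE_NEEDS,
    OUT_NO_FAMILY_CAREGIVER,
)
from .exceptions import ConfigurationError, ValidationError

_MARGIN_TOL = 1e-9

#: Outcome columns estimated from a classified respondent table.
DEFAULT_OUTCOMES = (
    "none",
    "paid_only",
    "fam1",
    "fam2",
    "fam3plus",
    "no_family_caregiver",
    "unmet_need",
    "care_needs",
    "no_care_needs",
    "care_needs_broad",
)


@dataclass
class MarginSpec:
    """Stratum shares of one stratifier; nonnegative, summing to 1."""

    stratifier: str
    shares: pd.Series

    def __post_init__(self) -> None:
        self.shares = pd.Series(self.shares, dtype=float)
        if (self.shares < 0).any():
            bad = self.shares.index[self.shares < 0].tolist()
            raise ValidationError(f"negative margin shares for strata {bad}")
        total = float(self.shares.sum())
        if abs(total - 1.0) > _MARGIN_TOL:
            raise ValidationError(
                f"margins over {self.stratifier!r} sum to {total!r}, expected 1"
            )

    @classmethod
    def from_mapping(cls, stratifier: str, shares: dict) -> "MarginSpec":
        return cls(stratifier, pd.Series(shares, dtype=float))

    def strata(self) -> list:
        return list(self.shares.index)


@dataclass
class SubgroupProbabilities:
    """Per-stratum outcome probabilities (proportion scale).

    ``table`` is indexed by stratum with one column per outcome.  All
    probabilities are conditional on stratum membership (denominator =
    everyone in the stratum).  When the full caregiver-category set plus
    the no-care-needs share is present, each row must sum to 1.
    """

    stratifier: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.table.to_numpy(dtype=float)
        finite = np.isfinite(values)
        if ((values < -_MARGIN_TOL) & finite).any() or ((values > 1 + _MARGIN_TOL) & finite).any():
            raise ValidationError(
                f"probabilities for {self.stratifier!r} outside [0, 1]"
            )
        full = set(CATEGORY_OUTCOMES) | {OUT_NO_CARE_NEEDS}
        if full.issubset(self.table.columns):
            sums = self.table[list(full)].sum(axis=1)
            bad = sums[(sums - 1.0).abs() > 1e-6].index.tolist()
            if bad:
                raise ValidationError(
                    f"category probabilities do not sum to 1 for strata {bad}"
                )

    def outcome(self, name: str) -> pd.Series:
        """Column lookup with derived aggregates (e.g. none + paid-only)."""
        if name in self.table.columns:
            return self.table[name]
        if name == OUT_NO_FAMILY_CAREGIVER and {"none", "paid_only"}.issubset(
            self.table.columns
        ):
            return self.table["none"] + self.table["paid_only"]
        raise ConfigurationError(
            f"outcome {name!r} not available for stratifier {self.stratifier!r}"
        )


class Transfer(NamedTuple):
    """Nonnegative mass moved from a donor stratum to a recipient stratum."""

    donor: object
    recipient: object
    mass: float


@dataclass
class TransferPlan:
    transfers: list[Transfer] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.transfers:
            if t.mass < 0:
                raise ValidationError(f"negative transfer mass in {t}")

    @property
    def total_moved(self) -> float:
        return float(sum(t.mass for t in self.transfers))

    def __iter__(self):
        return iter(self.transfers)

    def __len__(self) -> int:
        return len(self.transfers)


# ---------------------------------------------------------------------------
# Weighted estimation
# ---------------------------------------------------------------------------

def weighted_probabilities(
    data: pd.DataFrame,
    stratifier: str,
    outcomes: Iterable[str] = DEFAULT_OUTCOMES,
    weight_col: str = "weight",
) -> SubgroupProbabilities:
    """Weighted ratio estimates of outcome probabilities per stratum.

    ``data`` is a classified respondent table (see
    :func:`caregap.classify.classify_respondents`).  Strata with no
    respondents yield missing (NaN) probabilities with a warning, never a
    silent zero.
    """
    probs, _, _, _ = weighted_outcome_stats(data, stratifier, outcomes, weight_col)
    return SubgroupProbabilities(stratifier, probs)


def weighted_outcome_stats(
    data: pd.DataFrame,
    stratifier: str,
    outcomes: Iterable[str] = DEFAULT_OUTCOMES,
    weight_col: str = "weight",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Probabilities, standard errors, counts, and weight sums per stratum.

    Standard errors use the with-replacement approximation for a weighted
    proportion, ``sqrt(p (1-p) * sum(w^2)) / sum(w)``.
    """
    if stratifier not in data.columns:
        raise ConfigurationError(f"stratifier column {stratifier!r} not in data")
    if (data[weight_col] <= 0).any():
        raise ValidationError("all weights must be positive")

    indicators = _outcome_indicators(data, outcomes)
    w = data[weight_col].to_numpy(dtype=float)
    groups = data.groupby(stratifier, sort=True, observed=True)

    indices = groups.indices
    strata, prob_rows, se_rows, ns, sws = [], [], [], [], []
    for stratum in sorted(indices, key=str):
        idx = indices[stratum]
        strata.append(stratum)
        wg = w[idx]
        sw = wg.sum()
        sw2 = (wg**2).sum()
        p = (indicators.iloc[idx].to_numpy() * wg[:, None]).sum(axis=0) / sw
        se = np.sqrt(np.clip(p * (1 - p), 0, None) * sw2) / sw
        prob_rows.append(p)
        se_rows.append(se)
        ns.append(len(idx))
        sws.append(sw)
    probs = pd.DataFrame(prob_rows, index=strata, columns=indicators.columns)
    ses = pd.DataFrame(se_rows, index=strata, columns=indicators.columns)
    nobs = pd.Series(ns, index=strata, name="nobs")
    sumw = pd.Series(sws, index=strata, name="sum_weights")

    expected = _expected_strata(stratifier)
    if expected is not None:
        missing = [s for s in expected if s not in probs.index]
        if missing:
            warnings.warn(
                f"empty strata {missing} for stratifier {stratifier!r}; "
                "probabilities reported as missing",
                stacklevel=2,
            )
            probs = probs.reindex(list(expected))
            ses = ses.reindex(list(expected))
            nobs = nobs.reindex(list(expected), fill_value=0).astype(int)
            sumw = sumw.reindex(list(expected), fill_value=0.0)
    return probs, ses, nobs, sumw


def _outcome_indicators(data: pd.DataFrame, outcomes: Iterable[str]) -> pd.DataFrame:
    cols = {}
    category = data["caregiver_category"] if "caregiver_category" in data.columns else None
    cat_inverse = {v: k for k, v in CATEGORY_TO_OUTCOME.items()}
    for out in outcomes:
        if out in data.columns:
            cols[out] = data[out].astype(float)
        elif out == OUT_NO_CARE_NEEDS and "care_needs" in data.columns:
            cols[out] = (~data["care_needs"].astype(bool)).astype(float)
        elif out in cat_inverse and category is not None:
            cols[out] = (category == cat_inverse[out]).astype(float)
        else:
            raise ConfigurationError(f"cannot derive outcome {out!r} from data columns")
    return pd.DataFrame(cols, index=data.index)


def _expected_strata(stratifier: str):
    if stratifier == "family_structure":
        return FAMILY_STRUCTURES
    if stratifier == "family_size":
        return FAMILY_SIZE_LABELS
    return None


# ---------------------------------------------------------------------------
# Realignment
# ---------------------------------------------------------------------------

def realign_distribution(
    source: MarginSpec,
    probabilities: SubgroupProbabilities,
    target: MarginSpec,
    plan: TransferPlan | None = None,
) -> SubgroupProbabilities:
    """Move mass between strata so source margins become target margins.

    Transferred mass keeps the outcome distribution of its origin
    stratum; recipients therefore get mixture probabilities, donors keep
    theirs.  Raises :class:`ValidationError` if a donor would go negative
    or if the plan does not reproduce the target margins to 1e-9.
    """
    if set(source.strata()) != set(target.strata()):
        raise ValidationError("source and target margins cover different strata")
    if plan is None:
        plan = default_transfer_plan(source, target)

    strata = source.strata()
    s = source.shares.reindex(strata)
    out_mass = pd.Series(0.0, index=strata)
    in_mass = pd.Series(0.0, index=strata)
    table = probabilities.table.reindex(strata)
    in_outcome = pd.DataFrame(0.0, index=strata, columns=table.columns)

    for donor, recipient, mass in plan:
        if donor not in s.index or recipient not in s.index:
            raise ValidationError(f"transfer references unknown stratum: {donor}->{recipient}")
        out_mass[donor] += mass
        in_mass[recipient] += mass
        in_outcome.loc[recipient] += mass * table.loc[donor].to_numpy()

    residual = s - out_mass
    negative = residual[residual < -_MARGIN_TOL].index.tolist()
    if negative:
        raise ValidationError(
            f"infeasible transfer plan: donors {negative} would have negative residual mass"
        )
    realized = residual + in_mass
    mismatch = (realized - target.shares.reindex(strata)).abs()
    bad = mismatch[mismatch > 1e-9].index.tolist()
    if bad:
        raise ValidationError(
            f"transfer plan does not reproduce target margins for strata {bad}"
        )

    new_table = table.copy()
    for g in strata:
        total = residual[g] + in_mass[g]
        if in_mass[g] > 0 and total > 0:
            new_table.loc[g] = (
                residual[g] * table.loc[g].to_numpy() + in_outcome.loc[g].to_numpy()
            ) / total
    return SubgroupProbabilities(probabilities.stratifier, new_table)


def default_transfer_plan(source: MarginSpec, target: MarginSpec) -> TransferPlan:
    """Deterministic minimal-mass plan along the natural category order.

    Supported stratifiers: family structure (order U0, UB, US within the
    unmarried block then M0, MB, MS — mass flows from biological-only
    toward any-stepchildren within marital status) and family size (order
    0..4+, mass flows from smaller toward larger sizes when the target is
    larger-shifted).  Donors and recipients are matched in category order
    (northwest-corner rule), so the total moved mass equals half the L1
    distance between the margins — the minimum possible.
    """
    if source.stratifier != target.stratifier:
        raise ValidationError("source and target stratifiers differ")
    if source.stratifier == "family_structure":
        order = list(FAMILY_STRUCTURES)
    elif source.stratifier == "family_size":
        order = [s for s in source.strata()]
        order = sorted(order, key=_size_key)
    else:
        raise ConfigurationError(
            f"default transfer plans support family_structure/family_size, "
            f"not {source.stratifier!r}"
        )
    missing = [g for g in order if g not in source.shares.index]
    if missing:
        raise ValidationError(f"margins missing strata {missing}")

    diff = (source.shares - target.shares).reindex(order)
    donors = [[g, d] for g, d in diff.items() if d > _MARGIN_TOL]
    recipients = [[g, -d] for g, d in diff.items() if d < -_MARGIN_TOL]
    transfers: list[Transfer] = []
    i = j = 0
    while i < len(donors) and j < len(recipients):
        mass = min(donors[i][1], recipients[j][1])
        if mass > _MARGIN_TOL:
            transfers.append(Transfer(donors[i][0], recipients[j][0], mass))
        donors[i][1] -= mass
        recipients[j][1] -= mass
        if donors[i][1] <= _MARGIN_TOL:
            i += 1
        if recipients[j][1] <= _MARGIN_TOL:
            j += 1
    return TransferPlan(transfers)


def _size_key(stratum) -> int:
    text = str(stratum)
    return int(text.rstrip("+"))
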