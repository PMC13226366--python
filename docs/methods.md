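# Methods

This note documents the models and procedures implemented in `caregap`,
the parameters that matter, the numerical conventions, and what the
synthetic components do and do not emulate.

## Outcome measures

Eleven activities are probed: self-care (eating, bathing, toileting,
dressing), mobility (getting around inside, getting out of bed), and
household activities (laundry, meals, shopping, bills, medications).
Helpers are recorded per activity with a relationship label and a paid
flag; household activities additionally record the reason help was
received (health/functioning vs other).

* **Care needs (standard definition):** received help with any self-care
  or mobility activity, or with a household activity for health or
  functioning reasons, OR reported an unmet need. The **broad**
  sensitivity definition additionally counts unassisted difficulty;
  by construction broad prevalence ≥ standard prevalence on any sample.
* **Caregiver-network category:** the number of distinct *unpaid* helpers
  (relatives and others — "family caregivers", broadly defined) across
  counted activities, capped at 3+; zero unpaid but ≥1 paid helper is
  "paid-only" (applied whenever the unpaid count is zero, regardless of
  how many paid helpers there are); zero helpers is "none". Helpers who
  are paid are excluded from the family count by the paid flag alone,
  whatever their relationship. Distinct persons are identified by helper
  identity tokens; household help for non-health reasons is never counted.
* **Unmet need:** any of the adverse-consequence flags (e.g. having to
  stay in bed, going without bathing) is set. Unmet need implies care
  needs; respondents with no care needs have caregiver category
  "no care needs".

One structural consequence of these definitions: a respondent with zero
helpers can only have care needs through an unmet need, so within the
"no caregivers" category unmet need has probability 1, and attainable
unmet-need prevalence is bounded below by the no-caregivers share. The
packaged benchmark's "married, no children" row violates this bound
(10.9% no caregivers vs 8.8% unmet need), which the real survey can
produce through instrument details not modelled here; the synthetic
generator reproduces the caregiver categories exactly and attains the
closest feasible unmet-need rate (see below).

## Synthetic survey generator

`generate_respondents(n, margins, params, seed)` draws demographic strata
independently from supplied margins (default: the benchmark's 2022
distributions over age group, sex, race and family structure), child
counts coherent with the drawn family-structure code (1 + Poisson(1.2)
biological children for "biological only" strata, 1 + Poisson(0.8)
stepchildren plus Poisson(1.2) biological for stepfamily strata), and
weights from a lognormal(0, σ=0.5) scaled to mean 1 (design-based weights
are unavailable, so a right-skewed unit-mean distribution stands in).

Outcomes are drawn per respondent from `OutcomeParams`: a per-stratum
distribution over {no care needs, none, paid-only, 1, 2, 3+ family
caregivers} plus an unconditional unmet-need target. The default
parameters transcribe the benchmark's printed marginals — p(none),
p(paid-only) and p(unmet) per stratum — and back out the rest with two
declared conventions:

* total care-needs prevalence is `p(unmet) / 0.52`, applying a constant
  share of care-needs respondents with unmet needs (consistent with unmet
  needs affecting just over half of those with care needs overall);
* the residual care-needs mass is split across 1/2/3+ family caregivers
  as (0.563, 0.243, 0.194), a stylized version of the published category
  distribution among those with care needs.

Records are minimal but classifier-exact: one helped self-care/mobility
activity per family caregiver (distinct identity tokens), a single paid
helper for paid-only, a difficulty-plus-consequence record for "none",
and for no-care-needs respondents an unassisted difficulty with
probability 0.306 (driving the broad-definition margin) and, with
probability 0.10, household help for a non-health reason that the
classifiers must ignore. Unmet need is forced for category "none" and
assigned to helped categories with the conditional probability that hits
the stratum target when feasible, clipped to [0, 1] otherwise;
`OutcomeParams.effective_probabilities()` returns the rates the
classifier recovers in expectation, and parameter-recovery tests compare
against those.

What the generator does **not** emulate: survey skip logic, nonresponse
and design-based weighting, within-stratum heterogeneity in network size
beyond the declared split, correlation between demographic margins (they
are drawn independently), and nursing-home or nativity exclusions.
Passing recovery tests therefore demonstrates estimator and classifier
correctness under the declared generating process, not fidelity to any
real interview data.

## Weighted estimation and realignment

Subgroup probabilities are weighted ratio estimates,
`Σ w·y / Σ w` per stratum, with with-replacement standard errors
`sqrt(p(1−p)·Σw²)/Σw`. Estimates are scale-invariant in the weights and
reduce to unweighted proportions under constant weights. Empty strata are
reported as missing with a warning — never silently zero — and the
projection engine refuses to run with a missing required stratum.

Realignment moves nonnegative mass along declared donor→recipient pairs
until source margins equal target margins (validated to 1e-9). The moved
mass retains the outcome distribution of its origin stratum, so recipient
probabilities become mass-weighted mixtures while donors keep theirs;
total expected outcome mass (margins × probabilities) is conserved
exactly. The default plan orders categories naturally (family sizes
0→4+; family structure U0, UB, US, M0, MB, MS, so mass flows from
biological-only toward any-stepchildren within marital status) and
matches donors to recipients by the northwest-corner rule, which is
deterministic and moves the minimum possible total mass — half the L1
distance between the margins. Users can supply any explicit plan instead;
whether to realign jointly over structure × size or marginally per
stratifier is left to the caller (the package realigns marginally by
default, one stratifier at a time).

## Kinship microsimulation

Agents carry sex, race, birth/death years, an ordered union history, and
typed kin links (biological children, stepchildren, parents,
step-parents). Each simulated year applies events in a fixed order —
**mortality → divorce → marriage/remarriage → fertility** — chosen once
for reproducibility. Conventions:

* Ages are completed years with a hard cap at 100; the mortality schedule
  must equal 1 at the cap.
* Populations are closed and single-race (no intermarriage, no
  migration); cohabitation is not modelled as marriage.
* Spouse matching draws a target groom age of bride age + Normal(2, 3)
  truncated to [18, 100] and picks the closest available same-race
  candidate (deterministic tie-break by id). Unmatched candidates simply
  remain unmarried that year; remarriage is not allowed in the year a
  union dissolved.
* On marriage, each partner's biological children become the spouse's
  stepchildren, recorded symmetrically on the child; biological and step
  sets stay disjoint; **step ties persist after divorce and widowhood**
  (survey reports are known to under-count stepchildren from former
  marriages, so the simulation deliberately keeps them). Step-of-step
  chains are not propagated.
* Births attach to women via age-, parity- (capped at 4) and
  marital-status-specific rates; the current spouse becomes biological
  co-parent; nonmarital births have a single linked parent.
* Family structure and size in a reference year count only children alive
  that year, on the view that a deceased child cannot provide care.

Rate schedules are long-format tables (event, race, sex, age-or-duration,
parity, marital status, probability) validated on load; a missing cell
raises an error naming the cell, with optional declared fill values for
the non-mortality tables so stylized schedules need not enumerate rates
for children. `RateSchedule.stylized()` provides a demonstrative
schedule — Gompertz-like adult mortality (~0.001 at 50, ~0.1 at 80), a
bell-shaped marriage hazard peaking near age 26, duration-declining
divorce, fertility concentrated at ages 20–39 with a marital premium —
fixed once to yield qualitatively plausible late-life kin distributions
(~90% ever married, ~17% of 65+ with stepchildren in desk-scale runs).
It is not calibrated to any national series, and simulated 2030/2040
margins are expected to match published distributions only qualitatively;
quantitative projections should use the packaged benchmark margins or
user-supplied schedules.

Tabulations cover the full age-group × sex × race × structure × size
grid (half-open age bins [65,75), [75,85), [85,100]); scaling to an
external total preserves shares exactly. Identical configurations
(including the seed) produce bitwise-identical tabulations.

## Projection engine

Direct standardization as in the README: base-year probabilities are
frozen; growth-only scenarios use base-year shares with the overall rate,
factor scenarios use the factor's year-specific shares. Alternative
populations are handled either by explicit totals or by a fixed excluded
fraction *f* of the base year growing proportionally (totals scaled by
1/(1−f)); shares are reused under the proportional-growth assumption and
probabilities may be replaced by an expanded-sample set when available.
The caregiver-category distribution among those with care needs
renormalizes category masses to 100%; the mean network size uses
representative counts (0, 0, 1, 2, `three_plus_value`, default 3), and
whether paid-only counts as one caregiver is an explicit flag
(`include_paid`, default off) rather than a guess, since the published
mean is not reconstructible from printed category shares.

## Numerical conventions

* Internal arithmetic is unrounded; display rounding is half-up (ties
  away from zero) to one decimal, applied only at reporting.
* Margins must sum to 1 within 1e-9 (printed benchmark shares, which sum
  to 100 only up to rounding, are renormalized by the accessors).
* Probability-table coherence (categories + no-care-needs summing to 1)
  is validated at 1e-6 for estimated tables, 1e-9 for generator
  parameters.
* Reproduced benchmark projection cells are asserted within ±0.1 million
  and percentage increases within ±0.3 points of the printed values after
  display rounding, because the fixture's inputs are themselves printed
  to one decimal.
* Zero baselines make percentage increases undefined (reported missing
  with a warning); zero care-needs mass makes the category distribution
  undefined likewise.

## Known limitations

* The microsimulation is desk-scale and stylized; it demonstrates
  mechanism and supports invariant testing, not historical calibration.
* The synthetic survey's independence assumptions (margins drawn
  independently; one declared caregiver-count split for all strata)
  flatten real covariance between age, family structure and outcomes.
* Subgroup-specific and expanded-sample probability sets are not packaged
  (they are not printed in the benchmark); the engine accepts them as
  inputs when users can supply them.
* Hours and intensity of care, caregiver support ratios, joint projection
  of multiple factors, and nursing-home eligibility are out of scope.
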