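"""Packaged benchmark fixture.

A transcription of a published summary table of projected U.S. 65+
population counts (White and Black, U.S.-born; millions), percentage
distributions by age group, sex, race, family structure and family size
for 2022/2030/2040, and the 2022 prevalence of care-gap outcomes (care
needs with no family caregiver, split into "no caregivers" and "only paid
caregivers", and unmet need) by the same strata.

Every row carries its panel and row label so any transcription can be
audited cell by cell.  Counts are in millions; percentages are stored as
printed (one decimal) and converted to proportions by the accessor
functions.  Printed shares need not sum to exactly 100 (rounding); margin
accessors renormalize.
"""

from __future__ import annotations

import os

import pandas as pd

from .codes import STRATIFIERS
from .estimation import MarginSpec, SubgroupProbabilities
from .exceptions import ConfigurationError
from .projection import ProjectionInputs

YEARS = (2022, 2030, 2040)

#: Projected totals for the main population (millions), Panel A row "Overall".
TOTALS = {2022: 50.5, 2030: 59.9, 2040: 62.1}

#: Projected totals for the alternative population including foreign-born and
#: other racial/ethnic groups (millions), printed alongside the scenario table.
ALTERNATIVE_TOTALS = {2022: 62.8, 2030: 74.4, 2040: 77.2}

#: Printed 2022 baseline counts (millions) for the alternative population,
#: usable as inputs to ratio-scaled growth-only projections.
ALTERNATIVE_BASELINES_2022 = {"no_family_caregiver": 6.3, "unmet_need": 11.7}

# One tuple per table row:
# (stratifier, stratum,
#  count 2022, 2030, 2040 [millions, Panel A],
#  share 2022, 2030, 2040 [percent, Panel B],
#  no family caregiver, no caregivers, only paid, unmet need [percent, Panel C],
#  row label as printed)
_ROWS = [
    ("overall", "overall",
     50.5, 59.9, 62.1, 100.0, 100.0, 100.0, 11.0, 9.7, 1.3, 15.1, "Overall"),
    ("age_group", "65-74",
     28.8, 30.9, 25.9, 57.0, 51.6, 41.7, 9.4, 8.3, 1.1, 13.2, "Age 65-74"),
    ("age_group", "75-84",
     15.7, 21.2, 24.2, 31.1, 35.5, 39.0, 12.9, 12.1, 0.8, 16.0, "Age 75-84"),
    ("age_group", "85+",
     6.0, 7.7, 12.0, 11.9, 12.9, 19.3, 13.3, 9.3, 4.0, 22.7, "Age >= 85"),
    ("sex", "male",
     22.7, 27.0, 27.9, 45.0, 45.2, 45.0, 11.1, 9.8, 1.3, 12.8, "Men"),
    ("sex", "female",
     27.8, 32.8, 34.2, 55.0, 54.8, 55.0, 10.9, 9.6, 1.3, 17.0, "Women"),
    ("race", "White",
     44.8, 52.3, 53.1, 88.7, 87.4, 85.6, 10.9, 9.7, 1.2, 14.7, "White"),
    ("race", "Black",
     5.7, 7.5, 9.0, 11.3, 12.6, 14.4, 11.6, 9.6, 2.0, 18.7, "Black"),
    ("family_structure", "U0",
     2.5, 3.4, 3.9, 5.0, 5.8, 6.2, 17.3, 13.3, 4.0, 20.2,
     "No spouse, no biological children or stepchildren"),
    ("family_structure", "UB",
     10.4, 11.5, 12.1, 20.7, 19.3, 19.4, 12.8, 10.5, 2.3, 21.5,
     "No spouse, has biological children only"),
    ("family_structure", "US",
     8.2, 9.5, 10.3, 16.3, 15.9, 16.6, 14.5, 10.5, 4.0, 19.2,
     "No spouse, has stepchildren"),
    ("family_structure", "M0",
     2.6, 3.7, 3.5, 5.1, 6.2, 5.6, 10.9, 10.9, 0.0, 8.8,
     "Has spouse, no biological children or stepchildren"),
    ("family_structure", "MB",
     14.8, 17.4, 17.8, 29.3, 29.1, 28.6, 7.6, 7.4, 0.2, 10.2,
     "Has spouse, has biological children only"),
    ("family_structure", "MS",
     12.0, 14.2, 14.6, 23.7, 23.8, 23.5, 10.3, 10.2, 0.1, 13.3,
     "Has spouse, has stepchildren"),
    ("family_size", "0",
     2.5, 3.4, 3.9, 5.0, 5.8, 6.2, 17.3, 13.3, 4.0, 20.2, "Family size 0"),
    ("family_size", "1",
     5.1, 7.0, 7.2, 10.0, 11.7, 11.7, 10.1, 9.7, 0.4, 15.4, "Family size 1"),
    ("family_size", "2",
     7.8, 9.4, 9.8, 15.4, 15.8, 15.8, 13.0, 11.0, 2.0, 17.2, "Family size 2"),
    ("family_size", "3",
     10.0, 11.6, 11.8, 19.7, 19.4, 19.0, 8.4, 7.6, 0.8, 12.7, "Family size 3"),
    ("family_size", "4+",
     25.2, 28.4, 29.4, 49.8, 47.4, 47.3, 10.9, 9.7, 1.2, 14.9,
     "Family size >= 4"),
]

_COLUMNS = [
    "stratifier", "stratum",
    "count_2022", "count_2030", "count_2040",
    "share_2022", "share_2030", "share_2040",
    "no_family_caregiver", "none", "paid_only", "unmet_need",
    "row_label",
]


def benchmark_table() -> pd.DataFrame:
    """The full fixture as a tidy DataFrame (percent scale, as printed)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def benchmark_shares(stratifier: str, normalize: bool = True) -> pd.DataFrame:
    """Stratum shares as proportions; index strata, columns years.

    Printed percentages sum to 100 only up to rounding; ``normalize``
    rescales each year so shares sum to exactly 1.
    """
    sub = _stratum_rows(stratifier)
    df = pd.DataFrame(
        {year: sub[f"share_{year}"].to_numpy() / 100.0 for year in YEARS},
        index=sub["stratum"].to_numpy(),
    )
    if normalize:
        df = df / df.sum(axis=0)
    return df


def benchmark_margins(stratifier: str, year: int) -> MarginSpec:
    """Normalized :class:`MarginSpec` for one stratifier and year."""
    return MarginSpec(stratifier, benchmark_shares(stratifier)[year])


def benchmark_probabilities(stratifier: str) -> SubgroupProbabilities:
    """2022 outcome probabilities (proportion scale) for one stratifier."""
    sub = _stratum_rows(stratifier)
    table = (
        sub.set_index("stratum")[
            ["no_family_caregiver", "none", "paid_only", "unmet_need"]
        ]
        / 100.0
    )
    return SubgroupProbabilities(stratifier, table)


def benchmark_inputs(stratifiers: tuple[str, ...] | None = None) -> ProjectionInputs:
    """Projection inputs assembled from the packaged fixture."""
    strats = stratifiers or tuple(s for s in STRATIFIERS if s != "overall")
    strats = ("overall",) + tuple(s for s in strats if s != "overall")
    return ProjectionInputs(
        totals=dict(TOTALS),
        shares={s: benchmark_shares(s) for s in strats},
        probabilities={s: benchmark_probabilities(s).table for s in strats},
        base_year=2022,
    )


def _stratum_rows(stratifier: str) -> pd.DataFrame:
    if stratifier not in STRATIFIERS:
        raise ConfigurationError(
            f"unknown stratifier {stratifier!r}; expected one of {STRATIFIERS}"
        )
    table = benchmark_table()
    return table[table["stratifier"] == stratifier]


def build_fixture_files(directory: str) -> dict[str, str]:
    """Write the fixture as CSV files (table, totals, shares, probabilities).

    Returns a mapping of logical name -> path.  The shares and
    probabilities files are in tidy long format compatible with the
    package readers; the full table keeps the printed percent scale and
    row labels for auditing.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {}

    table = benchmark_table()
    paths["table"] = os.path.join(directory, "benchmark_table.csv")
    table.to_csv(paths["table"], index=False)

    totals = pd.DataFrame(
        {
            "year": list(TOTALS) + list(ALTERNATIVE_TOTALS),
            "population": ["main"] * len(TOTALS) + ["alternative"] * len(ALTERNATIVE_TOTALS),
            "total_millions": list(TOTALS.values()) + list(ALTERNATIVE_TOTALS.values()),
        }
    )
    paths["totals"] = os.path.join(directory, "totals.csv")
    totals.to_csv(paths["totals"], index=False)

    share_rows = []
    for stratifier in STRATIFIERS:
        shares = benchmark_shares(stratifier)
        for stratum, row in shares.iterrows():
            for year in YEARS:
                share_rows.append(
                    {"stratifier": stratifier, "stratum": stratum,
                     "year": year, "share": row[year]}
                )
    paths["shares"] = os.path.join(directory, "shares.csv")
    pd.DataFrame(share_rows).to_csv(paths["shares"], index=False)

    prob_rows = []
    for stratifier in STRATIFIERS:
        probs = benchmark_probabilities(stratifier)
        for stratum, row in probs.table.iterrows():
            for outcome, value in row.items():
                prob_rows.append(
                    {"stratifier": stratifier, "stratum": stratum,
                     "outcome": outcome, "value": value}
                )
    paths["probabilities"] = os.path.join(directory, "probabilities.csv")
    pd.DataFrame(prob_rows).to_csv(paths["probabilities"], index=False)
    return paths


def load_shares_csv(path: str, stratifier: str) -> pd.DataFrame:
    """Read a tidy shares CSV back into the wide (stratum x year) layout."""
    df = pd.read_csv(path)
    df = df[df["stratifier"] == stratifier]
    wide = df.pivot(index="stratum", columns="year", values="share")
    wide.columns = [int(c) for c in wide.columns]
    return wide


def load_probabilities_csv(path: str, stratifier: str) -> SubgroupProbabilities:
    df = pd.read_csv(path)
    df = df[df["stratifier"] == stratifier]
    table = df.pivot(index="stratum", columns="outcome", values="value")
    return SubgroupProbabilities(stratifier, table)
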