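"""Published per-specimen calls from the 22-tumor PDAC resection cohort
the method was developed on.

The table records, for each resected tumor, the recurrence outcome and the
number of distinct cluster types (CA19-9-only, STRA-only, dual; 0–3) found
by the pipeline after ROC dichotomization. One specimen has unknown
outcome and is excluded from all outcome statistics, leaving N = 21. The
outcome summary records how many of the recurrent cases recurred within
1, 2 and 3 years of resection.
"""

from __future__ import annotations

from io import StringIO

import numpy as np
import pandas as pd

from .stats import ChiSquareResult, heterogeneity_table

__all__ = [
    "study_table",
    "cohort_counts",
    "study_heterogeneity_table",
    "study_heterogeneity_chi2",
    "RECURRENCE_WITHIN_YEARS",
]

_STUDY_TABLE_CSV = """\
specimen_id,outcome,cluster_types
17213,Recurrence,1
20272,Recurrence,3
18760,Recurrence,3
16496,Recurrence,1
18137,Recurrence,3
19167,Recurrence,2
18371,Recurrence,3
1596,Recurrence,3
20333,Recurrence,3
19451,Recurrence,2
16250,Recurrence,2
17543,Recurrence,3
15658,Recurrence,3
20281,No Recurrence,3
19637,No Recurrence,1
19296,No Recurrence,0
19115,No Recurrence,1
18460,No Recurrence,0
16763,No Recurrence,1
14767,No Recurrence,1
16570,No Recurrence,3
20282,Unknown,2
"""

#: among the recurrent cases, the number recurring within 1/2/3 years
RECURRENCE_WITHIN_YEARS = {1: 7, 2: 11, 3: 12}


def study_table(include_unknown: bool = False) -> pd.DataFrame:
    """The per-specimen outcome / cluster-type table; by default the
    unknown-outcome specimen is excluded."""
    df = pd.read_csv(StringIO(_STUDY_TABLE_CSV), dtype={"specimen_id": str})
    if not include_unknown:
        df = df[df["outcome"] != "Unknown"].reset_index(drop=True)
    return df


def cohort_counts() -> dict:
    """Bookkeeping of the known-outcome cohort: totals and early-recurrence
    percentages."""
    df = study_table()
    total = len(df)
    recurrence = int((df["outcome"] == "Recurrence").sum())
    out = {
        "total": total,
        "recurrence": recurrence,
        "no_recurrence": total - recurrence,
    }
    for years, n in RECURRENCE_WITHIN_YEARS.items():
        out[f"recurrence_within_{years}yr"] = n
        out[f"recurrence_within_{years}yr_pct"] = round(100.0 * n / total, 1)
    return out


def study_heterogeneity_table() -> np.ndarray:
    """2×2 heterogeneity (≥ 2 cluster types) × recurrence table from the
    known-outcome specimens."""
    df = study_table()
    het = df["cluster_types"] >= 2
    rec = df["outcome"] == "Recurrence"
    return np.array(
        [
            [int((het & rec).sum()), int((het & ~rec).sum())],
            [int((~het & rec).sum()), int((~het & ~rec).sum())],
        ]
    )


def study_heterogeneity_chi2() -> ChiSquareResult:
    """Pearson χ² of cluster-type heterogeneity against recurrence in the
    study cohort."""
    df = study_table()
    return heterogeneity_table((df["cluster_types"] >= 2).values, (df["outcome"] == "Recurrence").astype(int).values)
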