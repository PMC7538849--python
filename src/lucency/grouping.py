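"""Solid-dominant vs non-solid-dominant cohort dichotomization.

Each imaging biomarker splits the cohort at a 0.6 threshold.  Ratio-type
biomarkers (RDC, RLC, DoC, LoSA_R, LoCA_R, Solidity) are thresholded on
their raw values; unbounded biomarkers (AT_R, LoSA, LoCA) are first mapped
into (0, 1) by an empirical-CDF mid-rank transform.  Biomarkers that
quantify the dense portion of a tumor send high values to the
solid-dominant (SD) group; biomarkers of the lucent portion send high
values to non-solid-dominant (NSD).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SOLID_POLARITY",
    "LUCENT_POLARITY",
    "NON_RATIO",
    "ecdf_normalize",
    "assign_groups",
    "group_table",
]

SOLID_POLARITY = frozenset({"rdc", "doc", "losa", "losa_r", "solidity"})
LUCENT_POLARITY = frozenset({"rlc", "at_r", "loca", "loca_r"})
NON_RATIO = frozenset({"at_r", "losa", "loca"})


def ecdf_normalize(values) -> np.ndarray:
    """Empirical-CDF mid-rank transform: v -> (rank(v) - 0.5) / n, ties averaged.

    Strictly order-preserving on distinct values; output lies in (0, 1).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("at least two values are required")
    return (rankdata(values, method="average") - 0.5) / len(values)


def assign_groups(
    ibm_name: str,
    values,
    threshold: float = 0.6,
    subject_ids=None,
    rlc_as_complement: bool = False,
) -> pd.DataFrame:
    """Dichotomize subjects into SD / NSD by one imaging biomarker.

    Parameters
    ----------
    ibm_name : one of the nine biomarker names.
    values : raw biomarker values across the cohort.
    threshold : dominance cut, default 0.6; the boundary value goes to the
        dominant side (>=).
    rlc_as_complement : group RLC through 1 - RLC with solid polarity, which
        makes the RLC partition identical to the RDC partition.
    """
    if ibm_name not in SOLID_POLARITY | LUCENT_POLARITY:
        raise ValueError(f"unknown imaging biomarker {ibm_name!r}")
    raw = np.asarray(values, dtype=float)
    work = raw
    polarity = "solid" if ibm_name in SOLID_POLARITY else "lucent"
    if ibm_name == "rlc" and rlc_as_complement:
        work = 1.0 - raw
        polarity = "solid"
    normalized = ecdf_normalize(work) if ibm_name in NON_RATIO else work
    if polarity == "solid":
        group = np.where(normalized >= threshold, "SD", "NSD")
    else:
        group = np.where(normalized >= threshold, "NSD", "SD")
    if subject_ids is None:
        subject_ids = np.arange(len(raw))
    return pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "ibm": ibm_name,
            "raw": raw,
            "normalized": normalized,
            "group": group,
        }
    )


def group_table(
    ibm_df: pd.DataFrame,
    threshold: float = 0.6,
    rlc_as_complement: bool = False,
    ibm_names=None,
) -> pd.DataFrame:
    """Long-format SD/NSD assignment for every biomarker column of an IBM table."""
    from .features import IBM_NAMES

    names = tuple(ibm_names) if ibm_names is not None else IBM_NAMES
    parts = [
        assign_groups(
            name,
            ibm_df[name].to_numpy(),
            threshold=threshold,
            subject_ids=ibm_df["subject_id"],
            rlc_as_complement=rlc_as_complement,
        )
        for name in names
    ]
    return pd.concat(parts, ignore_index=True)
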