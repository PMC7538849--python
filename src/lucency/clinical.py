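"""Clinical biomarker (CBM) encoding.

Nine covariates are carried into the models: gender, age, weight (lbs),
smoking years, histology, T/N/M stage and tumor size (mm).  Nominal
covariates map to {0, 1} in their listed category order; T, N and M stages
map each category to its cohort proportion (count in category / cohort size),
which keeps the design matrix dense; continuous covariates pass through
unchanged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CBM_COLUMNS",
    "GENDER_CATEGORIES",
    "HISTOLOGY_CATEGORIES",
    "STAGE_CATEGORIES",
    "encode_binary_nominal",
    "stage_proportion_encoding",
    "build_feature_table",
    "five_year_label",
]

GENDER_CATEGORIES = ("Male", "Female")
HISTOLOGY_CATEGORIES = ("Squamous", "Non-Squamous")
STAGE_CATEGORIES = {"t_stage": (1, 2, 3, 4), "n_stage": (0, 1, 2, 3), "m_stage": (0, 1)}

CBM_COLUMNS = (
    "gender", "age", "weight", "smoking_years", "histology",
    "t_stage", "n_stage", "m_stage", "tumor_size",
)


def encode_binary_nominal(value, categories) -> int:
    """Encode a two-category nominal value: first listed category -> 0, second -> 1."""
    categories = tuple(categories)
    if len(categories) != 2:
        raise ValueError("exactly two categories expected")
    try:
        return categories.index(value)
    except ValueError:
        raise ValueError(
            f"unknown category {value!r}; admissible values: {categories}"
        ) from None


def stage_proportion_encoding(stage_column, categories=None) -> dict:
    """Map each stage category to its cohort proportion.

    Each category encodes to (number of subjects in that category) / (cohort
    size); categories absent from the cohort encode to 0.
    """
    values = pd.Series(list(stage_column))
    if values.empty:
        raise ValueError("empty stage column")
    if categories is not None:
        bad = set(values) - set(categories)
        if bad:
            raise ValueError(f"invalid stage categories {sorted(bad)}; expected {categories}")
    n = len(values)
    counts = values.value_counts()
    mapping = {cat: 0.0 for cat in (categories if categories is not None else counts.index)}
    for cat, c in counts.items():
        mapping[cat] = c / n
    return mapping


def five_year_label(time, event, horizon: float = 5.0):
    """Binary endpoint: death within ``horizon`` years of surgery.

    Returns a float Series with 1.0 for death within the horizon, 0.0 for
    subjects followed beyond it, and NaN for subjects censored before the
    horizon without a death (unusable for classification but kept for
    time-to-event analyses).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    label = np.full(len(time), np.nan)
    label[time >= horizon] = 0.0
    label[(event == 1) & (time <= horizon)] = 1.0  # death at the horizon counts
    return pd.Series(label)


def build_feature_table(records: pd.DataFrame, stage_encoding: dict | None = None):
    """Encode a clinical table row-wise into numeric CBM features.

    Subjects with a missing value among the nine covariates are excluded with a
    logged reason.  Stage-proportion encodings are recomputed from the retained
    cohort unless a frozen ``stage_encoding`` mapping
    ``{column: {category: value}}`` is supplied.

    Returns ``(encoded, exclusions)`` where ``exclusions`` is a list of
    ``(subject_id, reason)`` pairs.
    """
    records = records.copy()
    missing_cols = [c for c in ("subject_id",) + CBM_COLUMNS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"clinical table missing columns: {missing_cols}")

    exclusions = []
    keep = np.ones(len(records), dtype=bool)
    for i, (_, row) in enumerate(records.iterrows()):
        nulls = [c for c in CBM_COLUMNS if pd.isna(row[c])]
        if nulls:
            reason = f"missing {', '.join(nulls)}"
            exclusions.append((row["subject_id"], reason))
            logger.info("excluding subject %s: %s", row["subject_id"], reason)
            keep[i] = False
    records = records.loc[keep].reset_index(drop=True)
    if records.empty:
        raise ValueError("no complete records to encode")

    out = pd.DataFrame({"subject_id": records["subject_id"]})
    out["gender"] = [encode_binary_nominal(v, GENDER_CATEGORIES) for v in records["gender"]]
    out["histology"] = [
        encode_binary_nominal(v, HISTOLOGY_CATEGORIES) for v in records["histology"]
    ]
    for col in ("age", "weight", "smoking_years", "tumor_size"):
        out[col] = records[col].astype(float)
    for col, cats in STAGE_CATEGORIES.items():
        if stage_encoding is not None and col in stage_encoding:
            mapping = {k: float(v) for k, v in stage_encoding[col].items()}
        else:
            mapping = stage_proportion_encoding(records[col], categories=cats)
        out[col] = records[col].map(mapping).astype(float)
    return out[["subject_id", *CBM_COLUMNS]], exclusions
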