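"""Five-year survival classification: stratified CV, ROC/AUC and IDI.

Three predictor pools are compared — clinical (CBM), imaging (IBM) and
hybrid (HBM = clinical + the prognostic imaging biomarkers) — across four
probabilistic classifier families.  Probabilities are pooled out-of-fold
from a stratified k-fold split shared across pools, so pool comparisons are
paired.  Discrimination is summarized by the ROC/AUC; the integrated
discrimination improvement (IDI) quantifies the gain of one pool over
another with a normal-approximation z test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .clinical import CBM_COLUMNS
from .features import IBM_NAMES

__all__ = [
    "CLASSIFIER_FAMILIES",
    "DEFAULT_HBM_IBMS",
    "feature_sets",
    "make_classifier",
    "stratified_folds",
    "cross_val_probs",
    "roc_auc",
    "idi",
    "compare_feature_sets",
    "ModelComparison",
]

CLASSIFIER_FAMILIES = ("lr", "rf", "svm", "ann")

# imaging biomarkers with univariable prognostic value, merged into the hybrid pool
DEFAULT_HBM_IBMS = ("rdc", "rlc", "losa_r", "loca_r")


def feature_sets(hbm_ibms=DEFAULT_HBM_IBMS) -> dict:
    """Column lists of the CBM / IBM / HBM predictor pools."""
    return {
        "CBM": list(CBM_COLUMNS),
        "IBM": list(IBM_NAMES),
        "HBM": list(CBM_COLUMNS) + list(hbm_ibms),
    }


def make_classifier(family: str, seed: int = 0):
    """A probabilistic classifier of the requested family, with per-fold scaling.

    Hyperparameters are fixed documented defaults: L2 logistic regression, a
    500-tree random forest, an RBF-kernel SVM with probability calibration,
    and a single-hidden-layer network with early stopping.
    """
    if family == "lr":
        clf = LogisticRegression(max_iter=1000, random_state=seed)
    elif family == "rf":
        clf = RandomForestClassifier(n_estimators=500, random_state=seed)
    elif family == "svm":
        from sklearn.calibration import CalibratedClassifierCV

        clf = CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed), ensemble=False)
    elif family == "ann":
        clf = MLPClassifier(
            hidden_layer_sizes=(16,),
            early_stopping=True,
            max_iter=500,
            random_state=seed,
        )
    else:
        raise ValueError(
            f"unknown classifier family {family!r}; expected one of {CLASSIFIER_FAMILIES}"
        )
    return make_pipeline(StandardScaler(), clf)


def stratified_folds(labels, k: int, seed: int) -> np.ndarray:
    """Assign each subject a fold index in 0..k-1, stratified by class.

    The cohort is split into its two label strata and subjects are assigned to
    folds uniformly at random within each stratum, so per-fold class counts
    differ from exact proportionality by at most one subject.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls!r} has only {len(idx)} members; use k <= {len(idx)}"
            )
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % k
    return folds


def cross_val_probs(features, labels, classifier_family, folds, seed: int = 0) -> np.ndarray:
    """Pooled out-of-fold event probabilities.

    Each subject's probability comes from a model fitted on the folds that
    exclude it; features are standardized on the training folds only.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        bad = np.argwhere(~np.isfinite(X))[0]
        col = bad[1]
        name = features.columns[col] if hasattr(features, "columns") else str(col)
        raise ValueError(f"non-finite feature for subject {bad[0]} in column {name}")
    folds = np.asarray(folds)
    probs = np.empty(len(y), dtype=float)
    for f in np.unique(folds):
        test = folds == f
        model = make_classifier(classifier_family, seed=seed) if isinstance(
            classifier_family, str
        ) else classifier_family
        model.fit(X[~test], y[~test])
        pos = list(model.classes_).index(1)
        probs[test] = model.predict_proba(X[test])[:, pos]
    return probs


def roc_auc(probs, labels):
    """ROC threshold sweep and the Mann-Whitney AUC (ties count 1/2).

    Returns ``(roc_points, auc)`` where ``roc_points`` is a DataFrame with
    columns fpr, tpr, threshold.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    fpr, tpr, thresh = roc_curve(labels, probs)
    # trapezoidal area over the full sweep == Mann-Whitney with half-ties
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh})
    return points, auc


def idi(probs_old, probs_new, labels):
    """Integrated discrimination improvement between two risk models.

    IDI is the change in discrimination slope: (mean new-model probability in
    events minus in non-events) minus the same contrast for the old model.
    The z statistic divides IDI by the combined standard error of the
    per-subject probability differences within each outcome group; the
    p-value is two-tailed normal.
    """
    p_old = np.asarray(probs_old, dtype=float)
    p_new = np.asarray(probs_new, dtype=float)
    y = np.asarray(labels).astype(int)
    if p_old.shape != p_new.shape or len(p_old) != len(y):
        raise ValueError("probability lists and labels must have equal length")
    ev, ne = p_new[y == 1] - p_old[y == 1], p_new[y == 0] - p_old[y == 0]
    if len(ev) < 2 or len(ne) < 2:
        raise ValueError("at least two subjects required in each outcome class")
    value = float(ev.mean() - ne.mean())
    se = np.sqrt(ev.var(ddof=1) / len(ev) + ne.var(ddof=1) / len(ne))
    if se == 0:
        z = 0.0 if value == 0 else np.inf * np.sign(value)
    else:
        z = value / se
    p = float(2 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return value, float(z), p


@dataclass
class ModelComparison:
    """Pooled out-of-fold results for every (classifier family, predictor pool)."""

    probs: dict = field(default_factory=dict)       # (family, set) -> array
    roc: dict = field(default_factory=dict)         # (family, set) -> DataFrame
    metrics: pd.DataFrame = None                    # family, set, auc
    idi: pd.DataFrame = None                        # family, old, new, idi, z, p
    folds: np.ndarray = None
    labels: np.ndarray = None


def compare_feature_sets(
    cohort: pd.DataFrame,
    sets: dict | None = None,
    families=CLASSIFIER_FAMILIES,
    k: int = 10,
    seed: int = 0,
    label_col: str = "five_year_label",
) -> ModelComparison:
    """Run the paired pool comparison on a cohort table.

    ``cohort`` holds one row per subject with all predictor columns and a
    binary endpoint column.  Folds are drawn once and shared across pools and
    families; IDI is reported for CBM->IBM and CBM->HBM within each family.
    """
    sets = feature_sets() if sets is None else sets
    labels = cohort[label_col].to_numpy().astype(int)
    folds = stratified_folds(labels, k=k, seed=seed)
    result = ModelComparison(folds=folds, labels=labels)
    metric_rows, idi_rows = [], []
    for family in families:
        for name, cols in sets.items():
            probs = cross_val_probs(cohort[cols], labels, family, folds, seed=seed)
            points, auc = roc_auc(probs, labels)
            result.probs[(family, name)] = probs
            result.roc[(family, name)] = points
            metric_rows.append({"family": family, "set": name, "auc": auc})
        for new in ("IBM", "HBM"):
            if "CBM" in sets and new in sets:
                value, z, p = idi(
                    result.probs[(family, "CBM")], result.probs[(family, new)], labels
                )
                idi_rows.append(
                    {"family": family, "old": "CBM", "new": new, "idi": value, "z": z, "p": p}
                )
    result.metrics = pd.DataFrame(metric_rows)
    result.idi = pd.DataFrame(idi_rows)
    return result
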