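"""Kaplan-Meier, log-rank and Cox proportional-hazards analyses.

Thin, contract-checked wrappers over lifelines: product-limit survival
curves with Greenwood variance, restricted-mean and median survival with
95% confidence intervals, the two-group log-rank test, and Cox models with
Efron tie handling, Wald intervals and a likelihood-ratio model test.
Backward elimination reproduces the covariate-retention step of a
univariable-screen-then-multivariable workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times

__all__ = [
    "km_estimate",
    "km_summary",
    "logrank",
    "cox_fit",
    "univariable_screen",
    "backward_select",
    "CoxResult",
]


def _validate(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("no subjects")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    return time, event


def km_estimate(time, event) -> KaplanMeierFitter:
    """Product-limit survival estimate with Greenwood confidence bands.

    Requires at least one observed event.  The fitted object exposes the step
    function (``survival_function_``) and its confidence interval.
    """
    time, event = _validate(time, event)
    if event.sum() == 0:
        raise ValueError("no events observed")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    return kmf


def _restricted_mean(kmf: KaplanMeierFitter, tau: float):
    """Area under the KM curve to ``tau`` and its standard error.

    The variance is the standard Greenwood-type sum over event times t_i <= tau
    of A_i^2 * d_i / (n_i * (n_i - d_i)), where A_i is the area under the curve
    from t_i to tau.
    """
    sf = kmf.survival_function_
    knots = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = knots <= tau
    t = np.append(knots[keep], tau)          # segment starts + closing endpoint
    s = surv[keep]                           # S on [t_k, t_{k+1})
    seg_area = s * np.diff(t)
    mean = float(seg_area.sum())

    table = kmf.event_table
    ev = table[(table["observed"] > 0) & (table.index <= tau)]
    var = 0.0
    for t_i, row in ev.iterrows():
        n_i, d_i = float(row["at_risk"]), float(row["observed"])
        if n_i - d_i <= 0:
            continue
        area_i = float(seg_area[t[:-1] >= t_i].sum())
        var += area_i**2 * d_i / (n_i * (n_i - d_i))
    return mean, float(np.sqrt(var))


def km_summary(time, event) -> dict:
    """Mean and median survival with 95% confidence intervals.

    The mean is the area under the survival curve restricted to the largest
    observed time (reported under ``restricted_to``); the median is the
    earliest time where S(t) <= 0.5, with a log-log transformed Greenwood
    interval, NaN when never reached.
    """
    time, event = _validate(time, event)
    kmf = km_estimate(time, event)
    t_max = float(time.max())
    mean, se = _restricted_mean(kmf, t_max)
    median = float(kmf.median_survival_time_)
    med_ci = median_survival_times(kmf.confidence_interval_)
    return {
        "mean": float(mean),
        "mean_ci": (float(mean - 1.96 * se), float(mean + 1.96 * se)),
        "restricted_to": t_max,
        "median": median,
        "median_ci": (
            float(med_ci.iloc[0, 0]),
            float(med_ci.iloc[0, 1]),
        ),
    }


def logrank(time, event, groups):
    """Two-group log-rank test; returns (chi-squared statistic, two-tailed p)."""
    time, event = _validate(time, event)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"exactly two nonempty groups required, got {len(labels)}")
    if event.sum() == 0:
        raise ValueError("no events observed")
    a, b = (groups == labels[0]), (groups == labels[1])
    res = logrank_test(time[a], time[b], event_observed_A=event[a], event_observed_B=event[b])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald CIs plus the model LR test."""

    summary: pd.DataFrame          # covariate, hr, ci_low, ci_high, p
    lr_chi2: float
    lr_df: int
    lr_p: float
    model: CoxPHFitter

    def hr(self, covariate: str) -> float:
        return float(self.summary.set_index("covariate").loc[covariate, "hr"])


def cox_fit(df: pd.DataFrame, covariates, time_col: str = "time",
            event_col: str = "event") -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) on the given covariates.

    Raises on non-convergence or monotone likelihood, naming the covariates
    involved.
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("at least one covariate required")
    n_events = int(df[event_col].sum())
    if n_events < len(covariates) + 1:
        raise ValueError(
            f"{n_events} events cannot support {len(covariates)} covariates"
        )
    cph = CoxPHFitter()
    data = df[[time_col, event_col, *covariates]]
    try:
        cph.fit(data, duration_col=time_col, event_col=event_col)
    except ConvergenceError as err:
        raise ValueError(
            f"Cox model failed to converge for covariates {covariates}: {err}"
        ) from err
    s = cph.summary
    summary = pd.DataFrame(
        {
            "covariate": s.index,
            "hr": s["exp(coef)"].to_numpy(),
            "ci_low": s["exp(coef) lower 95%"].to_numpy(),
            "ci_high": s["exp(coef) upper 95%"].to_numpy(),
            "p": s["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    lr = cph.log_likelihood_ratio_test()
    return CoxResult(
        summary=summary,
        lr_chi2=float(lr.test_statistic),
        lr_df=int(lr.degrees_freedom),
        lr_p=float(lr.p_value),
        model=cph,
    )


def univariable_screen(df: pd.DataFrame, candidates, alpha: float = 0.10,
                       time_col: str = "time", event_col: str = "event"):
    """Single-covariate Cox screens; returns (passing covariates, full table)."""
    rows = []
    passing = []
    for cov in candidates:
        res = cox_fit(df, [cov], time_col=time_col, event_col=event_col)
        row = res.summary.iloc[0].to_dict()
        rows.append(row)
        if row["p"] < alpha:
            passing.append(cov)
    return passing, pd.DataFrame(rows)


def backward_select(df: pd.DataFrame, candidates, alpha: float = 0.05,
                    time_col: str = "time", event_col: str = "event"):
    """Backward elimination from a candidate pool.

    Repeatedly drops the covariate with the largest Wald p while any
    p >= ``alpha``.  Returns the :class:`CoxResult` of the retained model, or
    None when every candidate is eliminated.
    """
    retained = list(candidates)
    result = None
    while retained:
        result = cox_fit(df, retained, time_col=time_col, event_col=event_col)
        worst = result.summary.sort_values("p", ascending=False).iloc[0]
        if worst["p"] < alpha:
            return result
        retained.remove(worst["covariate"])
        result = None
    return result
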