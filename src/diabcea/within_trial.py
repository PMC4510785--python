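"""Within-trial cost-effectiveness analysis.

Accumulates per-patient discounted costs and QALYs over 1-5 year horizons,
estimates covariate-adjusted incremental cost and QALYs by ordinary least
squares (outcome ~ arm + centre + age + sex + baseline HbA1c), and
classifies the incremental cost-effectiveness ratio (ICER).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from . import valuation as val
from .cohort import events_of

__all__ = [
    "IncrementalResult",
    "IcerResult",
    "adjusted_increment",
    "icer",
    "cumulative_table",
    "ADJUSTMENT_COVARIATES",
]

log = logging.getLogger(__name__)

ADJUSTMENT_COVARIATES = ("arm", "centre", "age", "sex", "hba1c_y0")


@dataclass(frozen=True)
class EstimateCI:
    estimate: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class IcerResult:
    """ICER classification over the four (dCost, dQALY) sign quadrants.

    classification: 'finite' (value = dCost/dQALY), 'infinite' (no QALY
    change bought at positive cost), 'dominated' (costs more, yields fewer
    QALYs), 'dominant' (costs less, yields more), or 'equivalent'.
    """

    classification: str
    value: float | None = None


@dataclass(frozen=True)
class IncrementalResult:
    horizon: int
    delta_cost: EstimateCI
    delta_qaly: EstimateCI
    icer: IcerResult


def icer(delta_cost: float, delta_qaly: float) -> IcerResult:
    if delta_qaly == 0.0:
        if delta_cost > 0.0:
            return IcerResult("infinite")
        if delta_cost < 0.0:
            return IcerResult("dominant")
        return IcerResult("equivalent", 0.0)
    if delta_qaly > 0.0:
        if delta_cost < 0.0:
            return IcerResult("dominant")
        return IcerResult("finite", delta_cost / delta_qaly)
    # delta_qaly < 0
    if delta_cost > 0.0:
        return IcerResult("dominated")
    return IcerResult("finite", delta_cost / delta_qaly)


def _design_matrix(df: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "const": 1.0,
            "arm_intensive": (df["arm"] == "intensive").astype(float),
            "centre_leicester": (df["centre"] == "Leicester").astype(float),
            "age": df["age"].astype(float),
            "sex_female": (df["sex"] == "female").astype(float),
            "hba1c_baseline": df["hba1c_y0"].astype(float),
        },
        index=df.index,
    )
    # drop covariates without variation (e.g. single-centre cohorts) so they
    # do not alias the intercept
    keep = ["const"] + [c for c in X.columns[1:] if X[c].nunique() > 1]
    return X[keep]


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy()
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name the offending columns: those whose removal restores full
        # column rank of the remainder
        collinear = []
        for j, name in enumerate(X.columns):
            rest = np.delete(A, j, axis=1)
            if np.linalg.matrix_rank(rest) == rank:
                collinear.append(name)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


def adjusted_increment(df: pd.DataFrame, outcome: str, alpha: float = 0.05) -> EstimateCI:
    """Arm coefficient (intensive - routine) of an OLS fit of ``outcome`` on
    arm, centre, age, sex and baseline HbA1c, with its normal-theory CI.

    Requires complete covariates (run after imputation) and >= 2 patients
    per arm.
    """
    for arm in ("routine", "intensive"):
        if (df["arm"] == arm).sum() < 2:
            raise ValueError(f"need >= 2 patients in arm {arm!r}")
    cols = ["age", "hba1c_y0", outcome]
    if df[cols].isna().any().any():
        raise ValueError("missing covariate or outcome values; impute first")
    X = _design_matrix(df)
    _check_rank(X)
    fit = sm.OLS(df[outcome].astype(float), X).fit()
    z = float(norm.ppf(1 - alpha / 2))
    b = float(fit.params["arm_intensive"])
    se = float(fit.bse["arm_intensive"])
    return EstimateCI(b, se, b - z * se, b + z * se)


def accumulate_cohort(
    cohort: pd.DataFrame,
    tables: val.ValuationTables,
    horizon: int,
    rate: float = 0.035,
    intervention_schedule: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Per-patient discounted (cost, qaly) over ``horizon`` years.

    ``intervention_schedule`` maps model year -> per-person GBP added to
    intensive-arm patients in that year (undiscounted amounts; discounting
    is applied here with everything else).
    """
    sched = intervention_schedule or {}
    costs = np.empty(len(cohort))
    qalys = np.empty(len(cohort))
    for i, (_, row) in enumerate(cohort.iterrows()):
        c, q = val.accumulate(events_of(row), horizon, rate, tables)
        if row["arm"] == "intensive":
            c += sum(
                amt * (1.0 + rate) ** -(t - 1)
                for t, amt in sched.items()
                if 1 <= t <= horizon
            )
        costs[i] = c
        qalys[i] = q
    out = cohort.copy()
    out["cost"] = costs
    out["qaly"] = qalys
    return out


def cumulative_table(
    cohort: pd.DataFrame,
    tables: val.ValuationTables,
    horizons=(1, 2, 3, 4, 5),
    rate: float = 0.035,
    intervention_schedule: dict[int, float] | None = None,
) -> pd.DataFrame:
    """One row per horizon: per-arm mean cumulative cost/QALYs, adjusted
    increments with 95% CIs, and the ICER classification.

    A patient enters the horizon-h row only if followed for at least h years
    (complete-horizon convention), so n shrinks with the horizon; a warning
    is logged when patients drop out.
    """
    rows = []
    for h in horizons:
        if h < 1:
            raise ValueError("horizon must be >= 1")
        sub = cohort[cohort["followup_years"] >= h - 1e-9]
        dropped = len(cohort) - len(sub)
        if dropped:
            log.warning("horizon %d: %d patients censored before horizon", h, dropped)
        acc = accumulate_cohort(sub, tables, h, rate, intervention_schedule)
        dc = adjusted_increment(acc, "cost")
        dq = adjusted_increment(acc, "qaly")
        ic = icer(dc.estimate, dq.estimate)
        r = {"horizon": h}
        for arm in ("routine", "intensive"):
            a = acc[acc["arm"] == arm]
            r[f"n_{arm}"] = len(a)
            r[f"mean_cost_{arm}"] = a["cost"].mean()
            r[f"mean_qaly_{arm}"] = a["qaly"].mean()
        r.update(
            delta_cost=dc.estimate,
            delta_cost_low=dc.ci_low,
            delta_cost_high=dc.ci_high,
            delta_qaly=dq.estimate,
            delta_qaly_low=dq.ci_low,
            delta_qaly_high=dq.ci_high,
            icer_class=ic.classification,
            icer_value=math.nan if ic.value is None else ic.value,
        )
        rows.append(r)
    return pd.DataFrame(rows)
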