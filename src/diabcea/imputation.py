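"""Multiple imputation under a multivariate normal model.

Missing risk-factor values (weight, height, smoking status, total
cholesterol, HDL, systolic blood pressure, HbA1c) are imputed by
multivariate-normal data augmentation: a Markov chain alternates drawing
missing cells from their conditional normal given the current parameters
with drawing (mean, covariance) from their posterior given the completed
data.  m completed datasets are taken from well-separated states of the
chain, and downstream estimates are pooled with Rubin's rules.

The Gibbs kernel is implemented here (I-step: conditional-normal draws per
distinct missing pattern; P-step: mean and covariance drawn from their
normal / inverse-Wishart posterior under a Jeffreys-type prior).  On top of
it sit the cohort plumbing: column selection, binary smoking handled on the
latent normal scale and thresholded at 0.5, the HDL <= cholesterol repair
rule, seed handling and the m-dataset bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import invwishart
from scipy.stats import t as t_dist

from .cohort import IMPUTABLE_VARS, MEASUREMENT_YEARS

__all__ = [
    "ImputationConfig",
    "impute",
    "repair_hdl",
    "rubins_pool",
    "PooledEstimate",
    "imputable_columns",
]


@dataclass
class ImputationConfig:
    m: int = 5
    variables: tuple = IMPUTABLE_VARS
    burn_in: int = 200  # Gibbs iterations discarded before the first draw
    thin: int = 100  # iterations between retained imputations
    seed: int = 0
    #: HDL repair mode, see repair_hdl
    strict_margin: bool = False

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if not self.variables:
            raise ValueError("variables must be non-empty")


def imputable_columns(df: pd.DataFrame, variables=IMPUTABLE_VARS) -> list[str]:
    """Concrete imputable columns present in a cohort panel: static
    weight/height plus the year-indexed measurement columns."""
    cols = []
    for v in variables:
        if v in ("weight", "height"):
            if v in df:
                cols.append(v)
        else:
            cols.extend(f"{v}_y{y}" for y in MEASUREMENT_YEARS if f"{v}_y{y}" in df)
    return cols


def repair_hdl(
    hdl: float, cholesterol: float, strict_margin: bool = False
) -> float:
    """Constraint repair after imputation: an HDL above total cholesterol is
    logically impossible, so it is reset to cholesterol - 0.1.

    With ``strict_margin`` the rule already triggers when HDL exceeds
    cholesterol - 0.1; by default only a genuine violation (HDL >
    cholesterol) is repaired.
    """
    limit = cholesterol - 0.1 if strict_margin else cholesterol
    if hdl > limit:
        return cholesterol - 0.1
    return hdl


def _repair_frame(df: pd.DataFrame, strict_margin: bool) -> pd.DataFrame:
    for y in MEASUREMENT_YEARS:
        h, c = f"hdl_y{y}", f"total_cholesterol_y{y}"
        if h in df and c in df:
            lim = df[c] - (0.1 if strict_margin else 0.0)
            viol = df[h] > lim
            df.loc[viol, h] = df.loc[viol, c] - 0.1
    return df


class GaussianDataAugmentation:
    """Gibbs sampler for the multivariate-normal imputation model.

    One ``update`` alternates the P-step (draw covariance from its
    inverse-Wishart posterior and the mean from its conditional normal,
    Jeffreys-type prior with a small ridge for numerical stability) with
    the I-step (draw missing cells from their conditional normal given the
    observed cells and current parameters, grouped by missing pattern).
    """

    def __init__(self, data: np.ndarray, rng: np.random.Generator, ridge: float = 1e-6):
        self.x = np.array(data, dtype=float)
        self.mask = np.isnan(self.x)
        self.rng = rng
        n, p = self.x.shape
        if n <= p + 2:
            raise ValueError(f"need more rows ({n}) than variables+2 ({p + 2})")
        col_means = np.nanmean(self.x, axis=0)
        self.x[self.mask] = np.take(col_means, np.nonzero(self.mask)[1])
        self.ridge = ridge * np.nanvar(self.x, axis=0).mean()
        # distinct missing patterns -> row indices
        self.patterns: dict[bytes, np.ndarray] = {}
        for key in np.unique(self.mask, axis=0):
            if not key.any():
                continue
            rows = np.flatnonzero((self.mask == key).all(axis=1))
            self.patterns[key.tobytes()] = (rows, np.flatnonzero(key))

    def update(self) -> None:
        n, p = self.x.shape
        xbar = self.x.mean(axis=0)
        r = self.x - xbar
        s = r.T @ r + self.ridge * np.eye(p)
        cov = invwishart.rvs(df=n - 1, scale=s, random_state=self.rng)
        mean = self.rng.multivariate_normal(xbar, cov / n, method="cholesky")
        for rows, miss in self.patterns.values():
            obs = np.setdiff1d(np.arange(p), miss)
            voo = cov[np.ix_(obs, obs)]
            vmo = cov[np.ix_(miss, obs)]
            vmm = cov[np.ix_(miss, miss)]
            resid = self.x[np.ix_(rows, obs)] - mean[obs]
            cm = mean[miss] + (vmo @ np.linalg.solve(voo, resid.T)).T
            cv = vmm - vmo @ np.linalg.solve(voo, vmo.T)
            cv = 0.5 * (cv + cv.T) + self.ridge * np.eye(len(miss))
            u = self.rng.standard_normal((len(rows), len(miss)))
            self.x[np.ix_(rows, miss)] = cm + u @ np.linalg.cholesky(cv).T


def impute(cohort: pd.DataFrame, config: ImputationConfig) -> list[pd.DataFrame]:
    """Return m completed copies of the cohort (observed cells unchanged,
    missing cells drawn from the posterior predictive), deterministic given
    ``config.seed``."""
    cols = imputable_columns(cohort, config.variables)
    if not cols:
        raise ValueError("no imputable columns found")
    sub = cohort[cols].astype(float)
    fully_missing = [c for c in cols if sub[c].isna().all()]
    if fully_missing:
        raise ValueError(f"variables 100% missing: {fully_missing}")

    if not sub.isna().any().any():
        return [cohort.copy() for _ in range(config.m)]

    binary_cols = [c for c in cols if c.startswith("smoker")]
    rng = np.random.default_rng(config.seed)
    kernel = GaussianDataAugmentation(sub.to_numpy(copy=True), rng)
    for _ in range(config.burn_in):
        kernel.update()
    completed: list[pd.DataFrame] = []
    for k in range(config.m):
        if k:
            for _ in range(config.thin):
                kernel.update()
        filled = pd.DataFrame(kernel.x.copy(), columns=cols, index=cohort.index)
        out = cohort.copy()
        for c in cols:
            out[c] = filled[c]
        for c in binary_cols:
            out[c] = (out[c] >= 0.5).astype(int)
        out = _repair_frame(out, config.strict_margin)
        completed.append(out)
    return completed


def stack_imputations(datasets: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate m completed cohorts with an ``imputation`` index column
    (the on-disk CSV layout)."""
    out = []
    for k, df in enumerate(datasets, start=1):
        d = df.copy()
        d.insert(0, "imputation", k)
        out.append(d)
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    total_variance: float
    within_variance: float
    between_variance: float
    df: float
    ci_low: float
    ci_high: float


def rubins_pool(estimates, variances, alpha: float = 0.05) -> PooledEstimate:
    """Rubin's rules: pooled point estimate is the mean of the per-imputation
    estimates; total variance = mean within-imputation variance +
    (1 + 1/m) x between-imputation variance.  The CI uses Rubin's
    degrees-of-freedom (normal when the between-variance is zero)."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2 or len(u) != m:
        raise ValueError("need m >= 2 estimates with matching variances")
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    total = w + (1.0 + 1.0 / m) * b
    if b > 0 and total > 0:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
        half = float(t_dist.ppf(1 - alpha / 2, df)) * np.sqrt(total)
    else:
        df = np.inf
        half = 1.959963984540054 * np.sqrt(total)
    return PooledEstimate(qbar, total, w, b, df, qbar - half, qbar + half)
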