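"""Multiple imputation by chained predictive mean matching; Rubin pooling.

Missing change-score cells are filled by predictive mean matching (PMM):
for each column with missing entries, a Bayesian linear regression on the
remaining columns (plus the condition indicator) yields predicted means, and
each missing cell receives the *observed* value of one of the k donors whose
predicted means lie closest — so imputed values always stay inside the
observed support.  Columns are visited in turn for a fixed number of sweeps
(chained equations), and the whole procedure is repeated m times with
independent randomness to produce m completed datasets.

Per-imputation estimates are combined with Rubin's rules: the pooled
estimate is the mean, the total variance adds the within-imputation mean and
(1 + 1/m) times the between-imputation variance, and degrees of freedom
follow Barnard & Rubin's small-sample formula when the complete-data df is
known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ImputedStack", "PooledEstimate", "pmm_impute", "pool_rubin"]


@dataclass
class ImputedStack:
    """m completed copies of a change-score table."""

    datasets: list[pd.DataFrame]
    m: int
    iterations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1 or len(self.datasets) != self.m:
            raise ValueError("stack must contain m >= 1 completed datasets")


@dataclass
class PooledEstimate:
    estimate: float
    se: float
    df: float
    within_var: float
    between_var: float


def _ridge_chol(xtx: np.ndarray, ridge: float) -> np.ndarray:
    """Cholesky of (X'X + ridge*diag) — the ridge keeps p ~ n designs stable."""
    lam = ridge * np.trace(xtx) / xtx.shape[0]
    return np.linalg.cholesky(xtx + lam * np.eye(xtx.shape[0]))


def _pmm_column(y: np.ndarray, x: np.ndarray, miss: np.ndarray, k: int,
                rng: np.random.Generator, ridge: float) -> np.ndarray:
    """Impute one column: type-1 PMM with a Bayesian parameter draw."""
    obs = ~miss
    x_obs, y_obs = x[obs], y[obs]
    n_obs, p = x_obs.shape
    chol = _ridge_chol(x_obs.T @ x_obs, ridge)
    beta_hat = np.linalg.solve(chol.T, np.linalg.solve(chol, x_obs.T @ y_obs))
    resid = y_obs - x_obs @ beta_hat
    dof = max(n_obs - p, 3)
    sigma2 = float(resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    z = rng.standard_normal(p)
    beta_star = beta_hat + np.sqrt(sigma2) * np.linalg.solve(chol.T, z)

    pred_obs = x_obs @ beta_hat
    pred_mis = x[miss] @ beta_star
    filled = np.empty(int(miss.sum()))
    k_eff = min(k, n_obs)
    for i, pm in enumerate(pred_mis):
        donors = np.argpartition(np.abs(pred_obs - pm), k_eff - 1)[:k_eff]
        filled[i] = y_obs[donors[rng.integers(k_eff)]]
    return filled


def pmm_impute(table: pd.DataFrame, condition: pd.Series | None = None,
               m: int = 5, iterations: int = 5, k_donors: int = 5,
               seed: int = 0, ridge: float = 1e-5) -> ImputedStack:
    """Chained-equations PMM over the columns of ``table``.

    Defaults follow standard chained-equations practice for this design:
    m = 5 completed datasets, 5 sweeps each, 5 donors.  Every column must
    retain some observed values; a fully missing column is an error naming
    the column.  Observed cells are identical across the m copies, and the
    procedure is reproducible from ``seed``.
    """
    data = table.astype(float)
    miss = data.isna()
    empty = [c for c in data.columns if miss[c].all()]
    if empty:
        raise ValueError(f"column(s) fully missing, cannot impute: {empty}")
    cols_missing = [c for c in data.columns if miss[c].any()]

    extra = None
    if condition is not None:
        codes = pd.Categorical(condition.loc[data.index]).codes.astype(float)
        extra = codes - codes.mean()

    master = np.random.SeedSequence(seed)
    datasets = []
    for stream in master.spawn(max(m, 1)):
        rng = np.random.default_rng(stream)
        filled = data.copy()
        for c in cols_missing:  # initial fill: random observed donors
            obs_vals = data[c].dropna().to_numpy()
            filled.loc[miss[c], c] = rng.choice(obs_vals, size=int(miss[c].sum()))
        for _ in range(max(iterations, 1)):
            for c in cols_missing:
                others = [o for o in data.columns if o != c]
                design = [np.ones(len(filled)), *[filled[o].to_numpy() for o in others]]
                if extra is not None:
                    design.append(extra)
                x = np.column_stack(design)
                filled.loc[miss[c], c] = _pmm_column(
                    filled[c].to_numpy(), x, miss[c].to_numpy(), k_donors, rng, ridge)
        datasets.append(filled)
    return ImputedStack(datasets=datasets, m=m, iterations=iterations, seed=seed)


def pool_rubin(estimates, ses, df_complete: float | None = None) -> PooledEstimate:
    """Combine per-imputation estimates and standard errors by Rubin's rules.

    With one imputation this is the identity.  When the between-imputation
    variance is zero (identical estimates) the pooled SE equals the mean
    within SE and the df reduce to the complete-data df (infinite when
    unknown).
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(ses, dtype=float) ** 2
    m = q.size
    if m == 0 or q.size != u.size:
        raise ValueError("need matching, non-empty estimates and SEs")
    q_bar = float(np.mean(q))
    w = float(np.mean(u))
    b = float(np.var(q, ddof=1)) if m > 1 else 0.0
    t = w + (1.0 + 1.0 / m) * b

    if b <= 0 or m == 1:
        df = float(df_complete) if df_complete is not None else np.inf
        return PooledEstimate(q_bar, float(np.sqrt(t)), df, w, b)

    r = (1.0 + 1.0 / m) * b / w
    df_large = (m - 1) * (1.0 + 1.0 / r) ** 2
    if df_complete is not None:  # Barnard-Rubin small-sample adjustment
        lam = (1.0 + 1.0 / m) * b / t
        df_obs = (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (1.0 - lam)
        df = 1.0 / (1.0 / df_large + 1.0 / df_obs)
    else:
        df = df_large
    return PooledEstimate(q_bar, float(np.sqrt(t)), float(df), w, b)
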