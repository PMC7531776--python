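"""Reward-history kernels: logistic regression of current return choices
on past rewards and past choices, per fly and population-averaged.

Row t of the design matrix carries the immediate reward R(t) (lag 0),
lagged rewards R(t-1)..R(t-M) and, optionally, lagged choices
c(t-1)..c(t-M); the response is c(t).  The first M trials are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .trials import ChoiceSequence

__all__ = [
    "RegressionSpec",
    "RegressionResult",
    "build_history_design",
    "fit_logistic",
    "fit_fly",
    "population_kernel",
]


@dataclass(frozen=True)
class RegressionSpec:
    m: int = 10
    include_choice_history: bool = True
    ridge: float = 0.0  # applied only after separation is detected when 0
    separation_ridge: float = 1e-4

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("history depth m must be >= 1")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    loglik: float
    loglik_null: float
    converged: bool
    separation: bool
    n_obs: int

    def coef(self, family: str) -> pd.Series:
        """Coefficients of one regressor family ('reward' or 'choice'),
        indexed by lag."""
        mask = self.params.index.str.startswith(f"{family}_lag")
        sub = self.params[mask]
        lags = [int(name.rsplit("lag", 1)[1]) for name in sub.index]
        return pd.Series(sub.to_numpy(), index=lags).sort_index()


def build_history_design(
    seq: ChoiceSequence, spec: RegressionSpec
) -> tuple[pd.DataFrame, np.ndarray]:
    """History design matrix and response for one fly/zone sequence."""
    r = np.asarray(seq.rewards, float)
    c = np.asarray(seq.choices, float)
    n, m = len(r), spec.m
    if n <= m:
        raise ValueError(f"sequence length {n} must exceed history depth {m}")
    cols: dict[str, np.ndarray] = {}
    for lag in range(m + 1):
        cols[f"reward_lag{lag}"] = r[m - lag:n - lag]
    if spec.include_choice_history:
        for lag in range(1, m + 1):
            cols[f"choice_lag{lag}"] = c[m - lag:n - lag]
    X = pd.DataFrame(cols)
    y = c[m:]
    return X, y


def _ridge_irls(
    X: np.ndarray, y: np.ndarray, penalty: float,
    max_iter: int = 200, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """IRLS with an L2 penalty on the slopes (intercept unpenalised).

    Used as a fallback when the unpenalised maximum-likelihood fit is
    unstable due to (quasi-)separation.  Returns (coef, se, loglik).
    """
    n, k = X.shape
    pen = np.full(k, penalty)
    pen[0] = 0.0  # first column is the constant
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        H = X.T @ (X * w[:, None]) + np.diag(pen)
        new = np.linalg.solve(H, X.T @ (w * z))
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = X.T @ (X * w[:, None]) + np.diag(pen)
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se, ll


def fit_logistic(
    X: pd.DataFrame, y: np.ndarray, spec: RegressionSpec | None = None
) -> RegressionResult:
    """Maximum-likelihood logistic fit with Wald t-statistics.

    Quasi-separation (non-convergence or exploding coefficients) is
    flagged and the model refit with a small ridge penalty so that the
    reported kernel stays finite.
    """
    spec = spec or RegressionSpec()
    Xc = sm.add_constant(X, has_constant="add")
    names = list(Xc.columns)
    arr = np.asarray(Xc, float)
    yv = np.asarray(y, float)
    n, k = arr.shape

    if spec.ridge == 0.0 and np.linalg.matrix_rank(arr) < k:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient; enable ridge regularization")

    separation = False
    converged = False
    beta = se = None
    ll = np.nan
    if spec.ridge > 0.0:
        separation_ridge = spec.ridge
        separation = True  # force penalised path
    else:
        separation_ridge = spec.separation_ridge
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(yv, arr).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            beta, se, ll = res.params, res.bse, float(res.llf)
            if (not converged or not np.all(np.isfinite(se))
                    or np.max(np.abs(beta)) > 30.0):
                separation = True
        except Exception:
            separation = True

    if separation:
        beta, se, ll = _ridge_irls(arr, yv, separation_ridge)
        converged = True

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=max(n - k, 1))
    p_null = np.clip(yv.mean(), 1e-12, 1 - 1e-12)
    ll_null = float(n * (p_null * np.log(p_null) + (1 - p_null) * np.log(1 - p_null)))
    return RegressionResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        loglik=ll, loglik_null=ll_null,
        converged=converged, separation=separation, n_obs=n,
    )


def fit_fly(seq: ChoiceSequence, spec: RegressionSpec | None = None) -> RegressionResult:
    spec = spec or RegressionSpec()
    X, y = build_history_design(seq, spec)
    return fit_logistic(X, y, spec)


def population_kernel(
    results: list[RegressionResult], alpha: float = 0.01
) -> pd.DataFrame:
    """Across-fly mean kernel with SEM and a significance mask.

    Significance of each lag is assessed by a one-sample t-test of the
    per-fly coefficients against zero; lags with p >= ``alpha`` are
    masked (``significant = False``).  Requires >= 2 flies.
    """
    if len(results) < 2:
        raise ValueError("population kernel needs >= 2 flies")
    names = results[0].params.index
    mat = np.vstack([r.params.reindex(names).to_numpy() for r in results])
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, pvals = stats.ttest_1samp(mat, 0.0, axis=0)
    rows = []
    for j, name in enumerate(names):
        if name == "const":
            family, lag = "intercept", -1
        else:
            family, lag_s = name.rsplit("_lag", 1)
            lag = int(lag_s)
        rows.append({
            "term": name, "family": family, "lag": lag,
            "mean": mean[j], "sem": sem[j], "p": pvals[j],
            "significant": bool(pvals[j] < alpha),
        })
    return pd.DataFrame(rows)
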