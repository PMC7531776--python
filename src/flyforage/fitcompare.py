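"""Model fitting and comparison: multistart maximum likelihood, AIC
selection, held-out predictive F1 and generative run-length tests.

The objective is the per-trial mean log likelihood

    L = (1/N) * sum_t [(1-c) log(1-P) + c log P]

with choice probabilities clamped to [1e-12, 1-1e-12] before the log.
AIC is computed on the total log likelihood N*L (the per-trial mean is
scale-inconsistent across flies); both quantities are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .rlmodels import MODELS, N_PARAMS, RLParams, forward_trace, \
    simulate_rl_agents_batch, simulate_reference_agents
from .trials import ChoiceSequence, run_length_histogram

__all__ = [
    "FitResult",
    "PredictiveScore",
    "DEFAULT_BOUNDS",
    "sequence_log_likelihood",
    "fit_mle_multistart",
    "aic_score",
    "select_model",
    "split_sequence",
    "predictive_f1",
    "generative_test",
]

P_CLAMP = 1e-12

#: multistart search box per parameter
DEFAULT_BOUNDS = {
    "alpha": (0.0, 1.0),
    "beta": (0.0, 50.0),
    "bias": (-1.0, 2.0),
    "alpha_f": (0.0, 1.0),
}


def _mean_loglik(alpha, beta, bias, phi, q0, rewards, choices):
    """Per-trial mean log likelihood of observed choices under the model."""
    n = rewards.shape[0]
    q = q0
    total = 0.0
    for t in range(n):
        z = beta * (bias - q)
        # numerically safe logistic
        if z > 0:
            ez = math.exp(-z)
            p = ez / (1.0 + ez)
        else:
            p = 1.0 / (1.0 + math.exp(z))
        if p < P_CLAMP:
            p = P_CLAMP
        elif p > 1.0 - P_CLAMP:
            p = 1.0 - P_CLAMP
        if choices[t]:
            total += math.log(p)
            q = q + alpha * (rewards[t] - q)
        else:
            total += math.log(1.0 - p)
            q = q - phi * q
    return total / n


try:  # optional numba acceleration; pure-python fallback is identical
    from numba import njit

    _mean_loglik = njit(cache=True, fastmath=False)(_mean_loglik)
except ImportError:  # pragma: no cover
    pass


@dataclass
class FitResult:
    params: RLParams
    logL_mean: float
    logL_total: float
    aic: float
    n_trials: int
    n_init: int
    best_init: int
    converged: bool


@dataclass
class PredictiveScore:
    tp: float
    fp: float
    fn: float
    precision: float
    recall: float
    f1: float


def sequence_log_likelihood(params: RLParams, seq: ChoiceSequence) -> float:
    """Per-trial mean log likelihood L of a sequence under ``params``."""
    if len(seq) == 0:
        raise ValueError("sequence must be nonempty")
    r = np.ascontiguousarray(seq.rewards, dtype=np.float64)
    c = np.ascontiguousarray(seq.choices, dtype=np.float64)
    return float(_mean_loglik(params.alpha, params.beta, params.bias,
                              params.phi, params.q0, r, c))


def _make_params(model: str, theta: np.ndarray, q0: float, fit_q0: bool) -> RLParams:
    alpha, beta, bias = theta[0], theta[1], theta[2]
    alpha_f = theta[3] if model == "FQaF" else None
    if fit_q0:
        q0 = theta[-1]
    return RLParams(model=model, alpha=float(np.clip(alpha, 0, 1)),
                    beta=float(max(beta, 0.0)), bias=float(bias),
                    alpha_f=None if alpha_f is None else float(np.clip(alpha_f, 0, 1)),
                    q0=float(max(q0, 0.0)))


def fit_mle_multistart(
    model: str,
    seq: ChoiceSequence,
    n_init: int = 100,
    seed=0,
    bounds: dict | None = None,
    q0: float = 0.0,
    fit_q0: bool = False,
    min_length: int = 10,
    tol: float = 1e-8,
) -> FitResult:
    """Bounded multistart maximum-likelihood fit of one model.

    ``n_init`` uniform random starts inside the parameter box are refined
    with L-BFGS-B (numeric gradients); the start with the highest mean
    log likelihood wins.  Deterministic under ``seed``.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if len(seq) < min_length:
        raise ValueError(f"sequence too short to fit (need >= {min_length})")
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    names = ["alpha", "beta", "bias"]
    if model == "FQaF":
        names.append("alpha_f")
    if fit_q0:
        names.append("q0")
        bnds.setdefault("q0", (0.0, 1.0))
    box = [bnds[n] for n in names]
    rng = np.random.default_rng(seed)
    r = np.ascontiguousarray(seq.rewards, dtype=np.float64)
    c = np.ascontiguousarray(seq.choices, dtype=np.float64)

    def neg(theta: np.ndarray) -> float:
        p = _make_params(model, theta, q0, fit_q0)
        val = _mean_loglik(p.alpha, p.beta, p.bias, p.phi, p.q0, r, c)
        if not np.isfinite(val):
            return 1e12
        return -val

    best_val = np.inf
    best_theta = None
    best_init = -1
    any_converged = False
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    for i in range(n_init):
        x0 = lo + (hi - lo) * rng.random(len(box))
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=box,
                                options={"ftol": tol, "maxiter": 500})
        if np.isfinite(res.fun) and res.fun < best_val:
            best_val = float(res.fun)
            best_theta = res.x
            best_init = i
        any_converged = any_converged or bool(res.success)
    if best_theta is None:
        raise RuntimeError("all optimizer starts failed")
    params = _make_params(model, best_theta, q0, fit_q0)
    n = len(seq)
    logl_mean = -best_val
    logl_total = n * logl_mean
    k = params.n_params + (1 if fit_q0 else 0)
    return FitResult(params=params, logL_mean=logl_mean, logL_total=logl_total,
                     aic=aic_score(logl_total, k), n_trials=n, n_init=n_init,
                     best_init=best_init, converged=any_converged)


def aic_score(logl_total: float, k: int) -> float:
    """AIC = 2k - 2 * total log likelihood."""
    return 2.0 * k - 2.0 * logl_total


def select_model(fits: dict[str, FitResult]) -> tuple[str, dict[str, float]]:
    """Minimum-AIC model; ties broken toward fewer parameters.

    Returns the winning model name and the per-model delta-AIC table.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fitted models to compare")
    best_aic = min(f.aic for f in fits.values())
    winner = min(fits.items(), key=lambda kv: (kv[1].aic, N_PARAMS[kv[0]]))[0]
    delta = {name: f.aic - best_aic for name, f in fits.items()}
    return winner, delta


def split_sequence(seq: ChoiceSequence) -> tuple[ChoiceSequence, ChoiceSequence]:
    """Chronological first-half / second-half split for predictive testing."""
    n = len(seq)
    h = n // 2
    def sub(sl):
        return ChoiceSequence(
            rewards=seq.rewards[sl], choices=seq.choices[sl],
            zone=None if seq.zone is None else seq.zone[sl],
            p_reward=seq.p_reward, fly_id=seq.fly_id,
            t_reward=None if seq.t_reward is None else seq.t_reward[sl])
    return sub(slice(0, h)), sub(slice(h, n))


def predictive_f1(
    params: RLParams, heldout: ChoiceSequence, threshold: float = 0.5
) -> PredictiveScore:
    """Trial-by-trial forecast of held-out choices, scored with F1.

    The model runs forward on the held-out data with the observed choices
    and rewards driving the value updates; a return is predicted when the
    model's choice probability exceeds ``threshold``.  TP/FP/FN are rates
    (fractions of held-out trials).  F1 is 0 when TP is 0.
    """
    if len(heldout) == 0:
        raise ValueError("held-out sequence is empty")
    trace = forward_trace(params, heldout.rewards, heldout.choices)
    pred = trace.p > threshold
    obs = heldout.choices.astype(bool)
    n = len(heldout)
    tp = float(np.sum(pred & obs)) / n
    fp = float(np.sum(pred & ~obs)) / n
    fn = float(np.sum(~pred & obs)) / n
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    return PredictiveScore(tp=tp, fp=fp, fn=fn, precision=precision,
                           recall=recall, f1=f1)


def _runs_per_sequence(c_row: np.ndarray, max_len: int) -> np.ndarray:
    counts = np.zeros(max_len, dtype=float)
    for length, k in run_length_histogram(c_row).items():
        counts[min(length, max_len) - 1] += k
    return counts


def generative_test(
    model: str,
    params: RLParams | None,
    conditions: list[float],
    n_seq: int = 1000,
    n_trials: int = 1000,
    seed=0,
    max_run_length: int = 20,
    response_prob: float = 0.5,
) -> dict[float, dict]:
    """Simulate fresh sequences per reward-probability condition and report
    return probabilities and run-length histograms with across-sequence SEM.

    ``model`` is an RL model name (with ``params``) or one of the
    reference agents ``'deterministic'`` / ``'random'``.
    """
    out: dict[float, dict] = {}
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    for p_reward, child in zip(conditions, ss.spawn(len(conditions))):
        if model in MODELS:
            if params is None:
                raise ValueError("RL generative test requires params")
            r, c = simulate_rl_agents_batch(params, p_reward, n_trials, n_seq, child)
        elif model in ("deterministic", "random"):
            rng_seeds = child.spawn(n_seq)
            rows = [simulate_reference_agents(model, p_reward, n_trials, s,
                                              response_prob=response_prob)
                    for s in rng_seeds]
            r = np.vstack([row.rewards for row in rows])
            c = np.vstack([row.choices for row in rows])
        else:
            raise ValueError(f"unknown model {model!r}")

        rew = r == 1
        with np.errstate(invalid="ignore"):
            p_ret_rew = np.where(rew.any(axis=1),
                                 (c * rew).sum(axis=1) / np.maximum(rew.sum(axis=1), 1),
                                 np.nan)
            p_ret_unrew = np.where((~rew).any(axis=1),
                                   (c * ~rew).sum(axis=1) / np.maximum((~rew).sum(axis=1), 1),
                                   np.nan)
        runs = np.vstack([_runs_per_sequence(c[i], max_run_length)
                          for i in range(n_seq)])
        out[p_reward] = {
            "p_return_rewarded": float(np.nanmean(p_ret_rew)),
            "p_return_rewarded_sem": float(np.nanstd(p_ret_rew, ddof=1)
                                           / np.sqrt(np.sum(np.isfinite(p_ret_rew)))),
            "p_return_unrewarded": float(np.nanmean(p_ret_unrew)),
            "p_return_unrewarded_sem": float(np.nanstd(p_ret_unrew, ddof=1)
                                             / np.sqrt(np.sum(np.isfinite(p_ret_unrew)))),
            "run_length_mean": runs.mean(axis=0),
            "run_length_sem": runs.std(axis=0, ddof=1) / np.sqrt(n_seq),
        }
    return out
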