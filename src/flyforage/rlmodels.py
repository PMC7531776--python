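"""Reinforcement-learning models of the binary return choice.

Three model variants share one value-update rule and one choice rule and
differ only in the forgetting rate applied to the value when no return
choice is made:

* ``RW``   — the unchosen value is frozen (forgetting rate 0),
* ``FQ``   — the value is forgotten at the learning rate ``alpha``,
* ``FQaF`` — the value is forgotten at an independent rate ``alpha_f``.

The value update is

    Q' = Q + alpha * (R - Q)     if the animal returned (c = 1)
    Q' = Q - phi * Q             otherwise

and the probability of a return on a trial with pre-trial value Q is the
logistic ``P = 1 / (1 + exp(beta * (bias - Q)))``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .trials import ChoiceSequence

__all__ = [
    "MODELS",
    "N_PARAMS",
    "RLParams",
    "ValueTrace",
    "update_value",
    "choice_probability",
    "forward_trace",
    "simulate_rl_agent",
    "simulate_rl_agents_batch",
    "simulate_reference_agents",
]

MODELS = ("RW", "FQ", "FQaF")

#: free parameters fitted per model (alpha, beta, bias [, alpha_f])
N_PARAMS = {"RW": 3, "FQ": 3, "FQaF": 4}


@dataclass(frozen=True)
class RLParams:
    """Parameter set identifying one model instance."""

    model: str = "FQ"
    alpha: float = 0.3
    beta: float = 5.0
    bias: float = 0.3
    alpha_f: float | None = None
    q0: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.beta < 0.0:
            raise ValueError("beta must be >= 0")
        if self.model == "FQaF":
            if self.alpha_f is None or not 0.0 <= self.alpha_f <= 1.0:
                raise ValueError("FQaF requires alpha_f in [0, 1]")
        if self.q0 < 0.0:
            raise ValueError("q0 must be >= 0")

    @property
    def phi(self) -> float:
        """Forgetting rate applied to the value on no-return trials."""
        if self.model == "RW":
            return 0.0
        if self.model == "FQ":
            return self.alpha
        return float(self.alpha_f)

    @property
    def n_params(self) -> int:
        return N_PARAMS[self.model]

    def with_values(self, **kw) -> "RLParams":
        return replace(self, **kw)


@dataclass
class ValueTrace:
    """Per-trial value (before the trial's update) and return probability."""

    q: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.q.shape != self.p.shape:
            raise ValueError("q and p must have equal length")


def _check_binary(name: str, v) -> int:
    v = int(v)
    if v not in (0, 1):
        raise ValueError(f"{name} must be 0 or 1, got {v}")
    return v


def update_value(params: RLParams, q: float, c, r) -> float:
    """One-step value update given the trial's choice ``c`` and reward ``r``."""
    if not np.isfinite(q):
        raise ValueError("q must be finite")
    c = _check_binary("c", c)
    r = _check_binary("r", r)
    if c == 1:
        return q + params.alpha * (r - q)
    return q - params.phi * q


def choice_probability(params: RLParams, q):
    """Probability of a return choice at value ``q`` (logistic in q)."""
    return 1.0 / (1.0 + np.exp(params.beta * (params.bias - np.asarray(q, float))))


def forward_trace(params: RLParams, rewards: np.ndarray, choices: np.ndarray) -> ValueTrace:
    """Run the model forward over observed data.

    ``q[t]`` is the value entering trial ``t`` (so ``q[0] == q0``) and
    ``p[t]`` the corresponding return probability; updates use the observed
    choice and reward of trial ``t``.
    """
    rewards = np.asarray(rewards)
    choices = np.asarray(choices)
    n = len(rewards)
    if len(choices) != n:
        raise ValueError("rewards and choices must have equal length")
    q = np.empty(n)
    qt = params.q0
    alpha, phi = params.alpha, params.phi
    for t in range(n):
        q[t] = qt
        if choices[t]:
            qt = qt + alpha * (rewards[t] - qt)
        else:
            qt = qt - phi * qt
    return ValueTrace(q=q, p=choice_probability(params, q))


def simulate_rl_agent(
    params: RLParams, p_reward: float, n_trials: int, seed
) -> tuple[ChoiceSequence, ValueTrace]:
    """Simulate one agent: per trial draw R ~ Bernoulli(p_reward), choose,
    update.  Returns the binary sequence and the full value trace."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= p_reward <= 1.0:
        raise ValueError("p_reward must be in [0, 1]")
    rng = np.random.default_rng(seed)
    r = np.empty(n_trials, dtype=np.int8)
    c = np.empty(n_trials, dtype=np.int8)
    q = np.empty(n_trials)
    p = np.empty(n_trials)
    qt = params.q0
    alpha, phi = params.alpha, params.phi
    for t in range(n_trials):
        r[t] = rng.random() < p_reward
        q[t] = qt
        p[t] = choice_probability(params, qt)
        c[t] = rng.random() < p[t]
        if c[t]:
            qt = qt + alpha * (r[t] - qt)
        else:
            qt = qt - phi * qt
    seq = ChoiceSequence(rewards=r, choices=c, p_reward=p_reward)
    return seq, ValueTrace(q=q, p=p)


def simulate_rl_agents_batch(
    params: RLParams, p_reward: float, n_trials: int, n_seq: int, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised simulation of ``n_seq`` independent agents.

    Returns (rewards, choices) as (n_seq, n_trials) int8 arrays.  Used by
    the generative test where 1000 sequences of 1000 trials are needed per
    condition.
    """
    if n_trials < 1 or n_seq < 1:
        raise ValueError("n_trials and n_seq must be >= 1")
    rng = np.random.default_rng(seed)
    alpha, beta, bias, phi = params.alpha, params.beta, params.bias, params.phi
    q = np.full(n_seq, float(params.q0))
    r_all = np.empty((n_seq, n_trials), dtype=np.int8)
    c_all = np.empty((n_seq, n_trials), dtype=np.int8)
    for t in range(n_trials):
        r = rng.random(n_seq) < p_reward
        p = 1.0 / (1.0 + np.exp(beta * (bias - q)))
        c = rng.random(n_seq) < p
        q = np.where(c, q + alpha * (r - q), q - phi * q)
        r_all[:, t] = r
        c_all[:, t] = c
    return r_all, c_all


def simulate_reference_agents(
    kind: str, p_reward: float, n_trials: int, seed, response_prob: float = 0.5
) -> ChoiceSequence:
    """Reference (non-learning) agents used as generative baselines.

    ``deterministic`` returns with ``response_prob`` only when rewarded and
    never otherwise; ``random`` returns with ``response_prob`` on every
    trial, independent of reward.
    """
    if kind not in ("deterministic", "random"):
        raise ValueError(f"kind must be 'deterministic' or 'random', got {kind!r}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= p_reward <= 1.0 or not 0.0 <= response_prob <= 1.0:
        raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    r = (rng.random(n_trials) < p_reward).astype(np.int8)
    u = rng.random(n_trials) < response_prob
    if kind == "deterministic":
        c = (u & (r == 1)).astype(np.int8)
    else:
        c = u.astype(np.int8)
    return ChoiceSequence(rewards=r, choices=c, p_reward=p_reward)
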