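"""Synthetic session generation.

Two levels of synthesis are provided so every downstream stage can be
tested without recorded data:

* trial level — agents emitting binary reward/choice sequences
  (:func:`simulate_choice_sequence`, :func:`make_regression_fixture`);
* trajectory level — a virtual linear-track arena with the closed-loop
  trigger rule (:func:`simulate_session_trajectory`,
  :func:`build_scripted_session`, :func:`apply_trigger`).

The trigger rule: a Bernoulli flash opportunity occurs only when the
animal crosses a reset zone and then enters the adjacent reward zone, in
that order; after a reward-zone entry the trigger disarms until the
reset zone is re-entered.  Dwelling inside the reward zone therefore
never re-fires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AgentSpec, ArenaConfig
from .kinematics import Trajectory
from .trials import ChoiceSequence
from . import rlmodels

__all__ = [
    "SessionRecord",
    "Visit",
    "simulate_choice_sequence",
    "make_regression_fixture",
    "apply_trigger",
    "build_scripted_session",
    "simulate_session_trajectory",
]


@dataclass
class SessionRecord:
    """One synthetic session: trajectory, stimulation log, settings."""

    trajectory: Trajectory
    stim_log: list  # (time_s, zone) pairs
    config: ArenaConfig
    seed: int | None = None


# ---------------------------------------------------------------------
# trial-level generators
# ---------------------------------------------------------------------


def simulate_choice_sequence(
    agent: AgentSpec, p_reward: float, n_trials: int, seed
) -> ChoiceSequence:
    """Binary reward/choice sequence emitted by one agent.

    Rewards are i.i.d. Bernoulli(p_reward); choices follow the agent rule
    (RL agents use the logistic choice rule on their running value).
    """
    if not 0.0 <= p_reward <= 1.0:
        raise ValueError("p_reward must be in [0, 1]")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if agent.kind == "rl":
        seq, _ = rlmodels.simulate_rl_agent(agent.rl_params, p_reward, n_trials, seed)
        return seq
    return rlmodels.simulate_reference_agents(
        agent.kind, p_reward, n_trials, seed, response_prob=agent.response_prob
    )


def make_regression_fixture(
    p_reward: float,
    n: int,
    responsiveness: float,
    seed,
    baseline: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Reward/choice vectors for the regression null control.

    Choices follow a reward with probability ``responsiveness`` and occur
    with a small baseline probability otherwise (``baseline=0`` reproduces
    the strict no-choice-on-unrewarded-trials construction, at the price
    of possible quasi-separation in the fit).
    """
    for name, v in (("p_reward", p_reward), ("responsiveness", responsiveness),
                    ("baseline", baseline)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rewards = (rng.random(n) < p_reward).astype(np.int8)
    u = rng.random(n)
    choices = np.where(rewards == 1, u < responsiveness, u < baseline).astype(np.int8)
    return rewards, choices


# ---------------------------------------------------------------------
# trigger rule
# ---------------------------------------------------------------------


def apply_trigger(time, x, config: ArenaConfig, seed) -> list[tuple[float, int]]:
    """Run the closed-loop trigger over a sampled path; return the stim log.

    Per zone, an armed flag is set on every entry into the reset zone and
    cleared on the next entry into the reward zone, at which moment a
    Bernoulli(p_zone) flash is drawn.
    """
    rng = np.random.default_rng(seed)
    time = np.asarray(time, float)
    x = np.asarray(x, float)
    stim: list[tuple[float, int]] = []
    for zone in (1, 2):
        p = config.stim_probability(zone)
        in_reward = config.in_reward_zone(x, zone)
        in_reset = config.in_reset_zone(x, zone)
        armed = False
        for i in range(len(x)):
            if in_reset[i] and (i == 0 or not in_reset[i - 1]):
                armed = True
            if in_reward[i] and (i == 0 or not in_reward[i - 1]):
                if armed:
                    if rng.random() < p:
                        stim.append((float(time[i]), zone))
                    armed = False
    stim.sort()
    return stim


# ---------------------------------------------------------------------
# scripted sessions (ground-truth itineraries)
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class Visit:
    """One scripted reward-zone visit.

    ``deep`` applies when the *next* visit is to the same zone: the
    interim excursion then touches the far reset band (so the visit does
    not count as a return) instead of staying in the middle.
    """

    zone: int
    rewarded: bool = False
    deep: bool = False


def _sample_waypoints(waypoints, speed: float, dt: float, t0: float = 0.0):
    """Constant-speed sampling along a piecewise-linear 1-D path."""
    wp = np.asarray(waypoints, float)
    seg = np.abs(np.diff(wp))
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    total = cum[-1]
    n = max(int(np.ceil(total / (speed * dt))) + 1, 2)
    s = np.linspace(0.0, total, n)
    xs = np.interp(s, cum, wp)
    ts = t0 + s / speed
    return ts, xs


def build_scripted_session(
    itinerary: list[Visit],
    config: ArenaConfig,
    speed: float = 10.0,
) -> tuple[SessionRecord, list[tuple[int, int, int]]]:
    """Deterministic session realising an explicit visit itinerary.

    Returns the session plus the ground-truth trial table as
    ``(zone, rewarded, returned)`` triples in chronological order.  A
    visit yields a trial iff the itinerary contains a later visit to the
    same zone (the final visit per zone is still open at session end).
    """
    if not itinerary:
        raise ValueError("itinerary must contain at least one visit")
    L = config.length
    depth = config.trigger_depth
    reward_pt = {1: config.reward_zone_depth / 2,
                 2: L - config.reward_zone_depth / 2}
    # shallow excursion turnaround: middle of the arena corridor
    mid_pt = {1: depth + (L - 2 * depth) * 0.35,
              2: L - depth - (L - 2 * depth) * 0.35}
    # deep excursion turnaround: inside the far reset band, short of the
    # far reward zone
    deep_pt = {1: L - config.reward_zone_depth - config.reset_zone_depth / 2,
               2: config.reward_zone_depth + config.reset_zone_depth / 2}

    waypoints = [L / 2]
    for i, v in enumerate(itinerary):
        waypoints.append(reward_pt[v.zone])
        nxt = itinerary[i + 1] if i + 1 < len(itinerary) else None
        if nxt is not None and nxt.zone == v.zone:
            waypoints.append(deep_pt[v.zone] if v.deep else mid_pt[v.zone])
    waypoints.append(L / 2)

    dt = 1.0 / config.sampling_rate
    ts, xs = _sample_waypoints(waypoints, speed, dt)
    ys = np.full_like(xs, config.width / 2)

    # reward-zone entries per zone correspond 1:1 to that zone's visits
    stim: list[tuple[float, int]] = []
    for zone in (1, 2):
        inz = config.in_reward_zone(xs, zone)
        entries = np.flatnonzero(inz & ~np.concatenate(([True], inz[:-1])))
        if inz[0]:
            entries = np.concatenate(([0], entries))
        visits = [v for v in itinerary if v.zone == zone]
        if len(entries) != len(visits):
            raise RuntimeError(
                f"zone {zone}: {len(entries)} reward entries for "
                f"{len(visits)} scripted visits")
        for idx, v in zip(entries, visits):
            if v.rewarded:
                stim.append((float(ts[idx]), zone))
    stim.sort()

    truth: list[tuple[int, int, int]] = []
    order = []
    for i, v in enumerate(itinerary):
        later = [j for j in range(i + 1, len(itinerary))
                 if itinerary[j].zone == v.zone]
        if not later:
            continue  # trial never terminated
        returned = int(later[0] == i + 1 and not v.deep)
        order.append((i, (v.zone, int(v.rewarded), returned)))
    truth = [rec for _, rec in sorted(order)]

    traj = Trajectory(time=ts, x=xs, y=ys, stim_events=list(stim))
    return SessionRecord(trajectory=traj, stim_log=stim, config=config), truth


# ---------------------------------------------------------------------
# stochastic closed-loop walk
# ---------------------------------------------------------------------


class _Walk:
    """Incremental 1-D-dominant walk with online trigger evaluation."""

    def __init__(self, config: ArenaConfig, rng: np.random.Generator,
                 speed: float, jitter: float, stop_hazard: float):
        self.cfg = config
        self.rng = rng
        self.dt = 1.0 / config.sampling_rate
        self.speed = speed
        self.jitter = jitter
        self.stop_hazard = stop_hazard
        self.t: list[float] = [0.0]
        self.x: list[float] = [config.length / 2]
        self.y: list[float] = [config.width / 2]
        self.stim: list[tuple[float, int]] = []
        self.armed = {1: False, 2: False}
        self.fired_flag = False
        self._classify_prev()

    def _classify_prev(self) -> None:
        x = self.x[-1]
        self.prev_reset = {z: bool(self.cfg.in_reset_zone(x, z)) for z in (1, 2)}
        self.prev_reward = {z: bool(self.cfg.in_reward_zone(x, z)) for z in (1, 2)}

    def _append(self, x: float) -> None:
        cfg, rng = self.cfg, self.rng
        x = float(np.clip(x, 0.0, cfg.length))
        y = float(np.clip(self.y[-1] + rng.normal(0.0, self.jitter * 0.5),
                          0.0, cfg.width))
        self.t.append(self.t[-1] + self.dt)
        self.x.append(x)
        self.y.append(y)
        for z in (1, 2):
            now_reset = bool(cfg.in_reset_zone(x, z))
            now_reward = bool(cfg.in_reward_zone(x, z))
            if now_reset and not self.prev_reset[z]:
                self.armed[z] = True
            if now_reward and not self.prev_reward[z]:
                if self.armed[z]:
                    if rng.random() < cfg.stim_probability(z):
                        self.stim.append((self.t[-1], z))
                        self.fired_flag = True
                    self.armed[z] = False
            self.prev_reset[z] = now_reset
            self.prev_reward[z] = now_reward

    def move_to(self, target: float, stop_scale: float = 1.0) -> None:
        rng = self.rng
        while abs(self.x[-1] - target) > self.speed * self.dt:
            if rng.random() < self.stop_hazard * stop_scale:
                # brief stop: sub-threshold drift for a few samples
                for _ in range(rng.integers(2, 8)):
                    self._append(self.x[-1] + rng.normal(0.0, 1e-4))
                continue
            step = np.sign(target - self.x[-1]) * self.speed * self.dt
            self._append(self.x[-1] + step + rng.normal(0.0, self.jitter))
        self._append(target)

    def local_search(self, duration_s: float, amplitude: float) -> None:
        """Reward-conditioned wiggle: elevated stop and reversal hazard."""
        n = int(duration_s / self.dt)
        centre = self.x[-1]
        direction = 1.0
        for _ in range(n):
            if self.rng.random() < 0.15:
                direction = -direction
            if self.rng.random() < 0.2:
                self._append(self.x[-1] + self.rng.normal(0.0, 1e-4))
            else:
                nxt = self.x[-1] + direction * self.speed * self.dt * 0.5
                if abs(nxt - centre) > amplitude:
                    direction = -direction
                    nxt = self.x[-1] + direction * self.speed * self.dt * 0.5
                self._append(nxt + self.rng.normal(0.0, self.jitter * 0.5))


def simulate_session_trajectory(
    config: ArenaConfig,
    agent: AgentSpec,
    duration: float,
    seed,
    speed: float = 8.0,
    jitter: float = 0.08,
    stop_hazard: float = 0.005,
    local_search_s: float = 1.5,
) -> SessionRecord:
    """Closed-loop stochastic session driven by an agent's return rule.

    The walk shuttles between reward zones; after each reward-zone visit
    the agent decides whether to return (re-enter the same reward zone
    before the far reset boundary) or to cross to the other side.  RL
    agents keep an independent value per zone.  Delivered stimulations
    transiently elevate the stop/turn hazard near the site.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    walk = _Walk(config, rng, speed=speed, jitter=jitter, stop_hazard=stop_hazard)
    L = config.length
    depth = config.trigger_depth
    reward_pt = {1: config.reward_zone_depth / 2, 2: L - config.reward_zone_depth / 2}

    q = {1: 0.0, 2: 0.0}
    if agent.kind == "rl":
        q = {1: agent.rl_params.q0, 2: agent.rl_params.q0}

    zone = int(rng.integers(1, 3))
    while walk.t[-1] < duration:
        walk.fired_flag = False
        walk.move_to(reward_pt[zone] + rng.normal(0.0, 0.5))
        rewarded = int(walk.fired_flag)
        if rewarded:
            walk.local_search(local_search_s, amplitude=config.reward_zone_depth / 2)
        if agent.kind == "rl":
            par = agent.rl_params
            p_ret = float(rlmodels.choice_probability(par, q[zone]))
            ret = rng.random() < p_ret
            q[zone] = rlmodels.update_value(par, q[zone], int(ret), rewarded)
        elif agent.kind == "deterministic":
            ret = rewarded and rng.random() < agent.response_prob
        else:
            ret = rng.random() < agent.response_prob
        if ret:
            lo = depth + 1.0
            hi = L - depth - 1.0
            mid = lo + (hi - lo) * rng.random() * 0.5
            walk.move_to(mid if zone == 1 else L - mid)
        else:
            zone = 2 if zone == 1 else 1

    t = np.asarray(walk.t)
    keep = t <= duration
    traj = Trajectory(time=t[keep], x=np.asarray(walk.x)[keep],
                      y=np.asarray(walk.y)[keep],
                      stim_events=[s for s in walk.stim if s[0] <= duration])
    return SessionRecord(trajectory=traj, stim_log=list(traj.stim_events),
                         config=config, seed=seed if isinstance(seed, int) else None)
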