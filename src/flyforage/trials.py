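"""Discrete trial structure of a session and return statistics.

A trial on one side of the track starts when the animal crosses that
side's reset zone and then enters its reward zone, and ends when it next
re-enters the same reset zone after having exited it outward.  A trial
counts as a *return* (c = 1) when, after leaving the reward and reset
zones, the path re-enters the same reward zone before reaching the
opposite side's reset-zone boundary.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trial",
    "ChoiceSequence",
    "SessionFilter",
    "segment_trials",
    "filter_sessions",
    "choice_sequence_from_trials",
    "return_statistics",
    "run_length_histogram",
    "first_reward_summary",
    "default_time_bins",
]


@dataclass(frozen=True)
class Trial:
    index: int
    zone: int
    t_enter_reset: float
    t_enter_reward: float
    t_end: float
    rewarded: int
    returned: int
    max_excursion_x: float

    def __post_init__(self) -> None:
        if self.zone not in (1, 2):
            raise ValueError("zone must be 1 or 2")
        if not (self.t_enter_reset <= self.t_enter_reward < self.t_end):
            raise ValueError("trial times must satisfy reset <= reward < end")
        if self.rewarded not in (0, 1) or self.returned not in (0, 1):
            raise ValueError("rewarded/returned must be binary")


@dataclass
class ChoiceSequence:
    """Ordered binary rewards R(t) and return choices c(t) for one fly/zone."""

    rewards: np.ndarray
    choices: np.ndarray
    zone: np.ndarray | None = None
    p_reward: float | None = None
    fly_id: str | int | None = None
    t_reward: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rewards = np.asarray(self.rewards, dtype=np.int8)
        self.choices = np.asarray(self.choices, dtype=np.int8)
        if self.rewards.shape != self.choices.shape or self.rewards.ndim != 1:
            raise ValueError("rewards and choices must be equal-length 1-D arrays")
        for name, arr in (("rewards", self.rewards), ("choices", self.choices)):
            if arr.size and not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} must be binary")
        if self.zone is not None:
            self.zone = np.asarray(self.zone)
            if self.zone.shape != self.rewards.shape:
                raise ValueError("zone labels must match sequence length")
        if self.t_reward is not None:
            self.t_reward = np.asarray(self.t_reward, dtype=float)
            if self.t_reward.shape != self.rewards.shape:
                raise ValueError("t_reward must match sequence length")

    def __len__(self) -> int:
        return len(self.rewards)

    def to_frame(self) -> pd.DataFrame:
        d = {"trial": np.arange(len(self)), "reward": self.rewards,
             "choice": self.choices}
        if self.zone is not None:
            d["zone"] = self.zone
        if self.t_reward is not None:
            d["t_reward_s"] = self.t_reward
        return pd.DataFrame(d)


def _entries(mask: np.ndarray) -> np.ndarray:
    """Indices where a boolean trace switches False -> True."""
    m = np.asarray(mask, dtype=bool)
    return np.flatnonzero(m & ~np.concatenate(([True], m[:-1])))


def segment_trials(session) -> list[Trial]:
    """Segment a :class:`~flyforage.synthgen.SessionRecord` into trials.

    Runs one state machine per zone over the sample-wise zone-membership
    traces and stamps rewarded flags from the session's stimulation log.
    Trials still in progress at session end are dropped; a finished trial
    whose return outcome is still undecided at session end is dropped too.
    """
    traj = session.trajectory
    cfg = session.config
    t = np.asarray(traj.time, float)
    x = np.asarray(traj.x, float)
    out: list[Trial] = []
    for zone in (1, 2):
        out.extend(_segment_zone(t, x, cfg, zone, session.stim_log))
    out.sort(key=lambda tr: tr.t_enter_reward)
    return [
        Trial(index=i, zone=tr.zone, t_enter_reset=tr.t_enter_reset,
              t_enter_reward=tr.t_enter_reward, t_end=tr.t_end,
              rewarded=tr.rewarded, returned=tr.returned,
              max_excursion_x=tr.max_excursion_x)
        for i, tr in enumerate(out)
    ]


def _segment_zone(t, x, cfg, zone: int, stim_log) -> list[Trial]:
    in_reward = cfg.in_reward_zone(x, zone)
    in_reset = cfg.in_reset_zone(x, zone)
    far = cfg.beyond_far_reset_boundary(x, zone)
    wall_dist = np.abs(cfg._wall_distance(x, zone))
    stim_times = np.array([ts for ts, z in stim_log if z == zone], dtype=float)

    # phases: seek reset entry -> armed -> visiting (reward/reset, until
    # exiting the reset zone outward) -> out (trial open)
    SEEK, ARMED, VISIT, OUT = range(4)
    phase = SEEK
    t_reset = t_reward = math.nan
    # trial whose end time is known but whose return outcome is not yet:
    # [t_enter_reset, t_enter_reward, t_end, max_excursion, far_seen]
    pending: list | None = None
    max_exc = 0.0
    far_seen = False  # far boundary reached since exiting the reset zone
    trials: list[Trial] = []

    def close(rec, returned: int) -> None:
        t0, t1, t2, exc, _ = rec
        rewarded = int(np.any((stim_times >= t1) & (stim_times < t2)))
        trials.append(Trial(index=0, zone=zone, t_enter_reset=t0,
                            t_enter_reward=t1, t_end=t2, rewarded=rewarded,
                            returned=int(returned), max_excursion_x=exc))

    for i in range(len(t)):
        if phase == SEEK:
            if in_reset[i]:
                phase, t_reset = ARMED, t[i]
        elif phase == ARMED:
            if pending is not None:
                if far[i]:
                    pending[4] = True
                if in_reward[i]:
                    close(pending, 0 if pending[4] else 1)
                    pending = None
            if in_reward[i]:
                phase, t_reward, max_exc = VISIT, t[i], wall_dist[i]
        elif phase == VISIT:
            max_exc = max(max_exc, wall_dist[i])
            if not in_reward[i] and not in_reset[i]:
                phase = OUT
                far_seen = bool(far[i])
        else:  # OUT
            max_exc = max(max_exc, wall_dist[i])
            far_seen = far_seen or bool(far[i])
            if in_reset[i]:
                # this reset entry both ends the open trial and arms the next
                pending = [t_reset, t_reward, t[i], max_exc, far_seen]
                phase, t_reset = ARMED, t[i]
    return trials


@dataclass
class SessionFilter:
    trials: list[Trial]
    excluded: bool
    n_trials: int


def filter_sessions(trials: list[Trial], min_trials: int = 50) -> SessionFilter:
    """Exclude flies with fewer than ``min_trials`` trials (boundary kept)."""
    n = len(trials)
    return SessionFilter(trials=trials, excluded=n < min_trials, n_trials=n)


def choice_sequence_from_trials(
    trials: list[Trial], zone: int | None = None,
    p_reward: float | None = None, fly_id=None,
) -> ChoiceSequence:
    """Extract the binary reward/choice sequence, optionally for one zone."""
    sel = [tr for tr in trials if zone is None or tr.zone == zone]
    return ChoiceSequence(
        rewards=np.array([tr.rewarded for tr in sel], dtype=np.int8),
        choices=np.array([tr.returned for tr in sel], dtype=np.int8),
        zone=np.array([tr.zone for tr in sel]),
        p_reward=p_reward,
        fly_id=fly_id,
        t_reward=np.array([tr.t_enter_reward for tr in sel], dtype=float),
    )


def return_statistics(trials: list[Trial], window: int = 5) -> dict:
    """Per-zone / per-outcome return probabilities and a centred moving average.

    Conditioning sets that are empty yield NaN (undefined), never zero.
    """
    if not trials:
        raise ValueError("need at least one trial")
    df = pd.DataFrame({
        "zone": [tr.zone for tr in trials],
        "rewarded": [tr.rewarded for tr in trials],
        "returned": [tr.returned for tr in trials],
    })

    def cond_mean(mask) -> float:
        sub = df.loc[mask, "returned"]
        return float(sub.mean()) if len(sub) else float("nan")

    stats = {
        "overall": float(df["returned"].mean()),
        "by_zone_outcome": {
            (z, rw): cond_mean((df.zone == z) & (df.rewarded == rw))
            for z in sorted(df.zone.unique()) for rw in (0, 1)
        },
        "p_return_rewarded": cond_mean(df.rewarded == 1),
        "p_return_unrewarded": cond_mean(df.rewarded == 0),
        "moving_average": df["returned"].rolling(window, center=True).mean().to_numpy(),
    }
    return stats


def run_length_histogram(choices) -> Counter:
    """Histogram of lengths of maximal blocks of consecutive returns (c=1)."""
    c = np.asarray(choices).astype(np.int8)
    if c.size and not np.isin(c, (0, 1)).all():
        raise ValueError("choices must be binary")
    hist: Counter = Counter()
    run = 0
    for v in c:
        if v:
            run += 1
        elif run:
            hist[run] += 1
            run = 0
    if run:
        hist[run] += 1
    return hist


def default_time_bins() -> np.ndarray:
    """Delay-bin edges (s) for the first-reward analysis: 0.03 s steps to 1 s,
    0.1 s steps to 9 s, 50 s steps from 10 to 200 s, 100 s steps 300-1000 s."""
    edges = np.concatenate([
        np.arange(0.0, 1.0, 0.03),
        np.arange(1.0, 9.0 + 1e-9, 0.1),
        np.arange(10.0, 200.0 + 1e-9, 50.0),
        np.arange(300.0, 1000.0 + 1e-9, 100.0),
    ])
    return np.unique(edges)


def first_reward_summary(
    sequences: list[ChoiceSequence],
    trial_bins: np.ndarray | None = None,
    time_bins: np.ndarray | None = None,
) -> dict:
    """Return-on-first-reward fraction versus first-reward delay.

    For every fly the first rewarded trial is located; flies with no
    rewarded trial are excluded.  Fractions of flies that returned on that
    trial are reported per trial-index bin and, when timestamps are
    available, per wall-clock delay bin.  Also splits the return
    probability on subsequent rewarded trials by the first-reward response.
    """
    rows = []
    for k, seq in enumerate(sequences):
        idx = np.flatnonzero(seq.rewards == 1)
        if idx.size == 0:
            continue
        first = int(idx[0])
        later = idx[1:]
        rows.append({
            "fly": seq.fly_id if seq.fly_id is not None else k,
            "first_trial": first,
            "first_time": float(seq.t_reward[first]) if seq.t_reward is not None else np.nan,
            "returned_on_first": int(seq.choices[first]),
            "later_return_prob": float(seq.choices[later].mean()) if later.size else np.nan,
        })
    if not rows:
        raise ValueError("no fly with a rewarded trial")
    df = pd.DataFrame(rows)

    if trial_bins is None:
        trial_bins = np.arange(0, 31, 3)
    tb = pd.cut(df["first_trial"], bins=trial_bins, right=False)
    by_trial = (
        df.groupby(tb, observed=True)["returned_on_first"]
        .agg(fraction="mean", n_flies="size").reset_index()
    )

    by_time = None
    if df["first_time"].notna().any():
        if time_bins is None:
            time_bins = default_time_bins()
        wb = pd.cut(df["first_time"], bins=time_bins, right=False)
        by_time = (
            df.dropna(subset=["first_time"])
            .groupby(wb, observed=True)["returned_on_first"]
            .agg(fraction="mean", n_flies="size").reset_index()
        )

    split = {
        "later_return_given_first_return": float(
            df.loc[df.returned_on_first == 1, "later_return_prob"].mean()),
        "later_return_given_no_first_return": float(
            df.loc[df.returned_on_first == 0, "later_return_prob"].mean()),
    }
    return {"per_fly": df, "by_trial_bin": by_trial, "by_time_bin": by_time,
            "first_response_split": split}
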