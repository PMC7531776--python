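"""Arena geometry, run configuration and deterministic seeding.

The arena is a linear track.  Each end carries two nested zones: an
outermost *reward* (trigger) zone and, immediately inboard of it, a
*reset* zone.  A probabilistic stimulation can fire only when the animal
crosses the reset zone and then enters the reward zone, in that order;
re-arming requires another reset-zone entry.  Zone membership uses
half-open intervals measured from the nearer wall, so the layout is
mirror-symmetric.
"""

from __future__ import annotations

import tomllib
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np

__all__ = [
    "ArenaConfig",
    "AgentSpec",
    "RunConfig",
    "subseed",
    "spawn_rng",
    "load_run_config",
]


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and stimulation settings of one linear-track arena.

    Lengths are millimetres, times seconds, rates hertz.
    """

    length: float = 50.0
    width: float = 5.0
    reward_zone_depth: float = 6.0
    reset_zone_depth: float = 3.0
    stim_probability_zone1: float = 0.0
    stim_probability_zone2: float = 0.0
    stim_duration: float = 0.05
    sampling_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.reward_zone_depth + self.reset_zone_depth >= self.length / 2:
            raise ValueError(
                "reward_zone_depth + reset_zone_depth must be < length/2"
            )
        for name in ("stim_probability_zone1", "stim_probability_zone2"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.stim_duration < 0:
            raise ValueError("stim_duration must be >= 0")

    # -- geometry -----------------------------------------------------

    def stim_probability(self, zone: int) -> float:
        return {1: self.stim_probability_zone1, 2: self.stim_probability_zone2}[zone]

    def _wall_distance(self, x: np.ndarray | float, zone: int) -> np.ndarray | float:
        """Distance from the wall belonging to ``zone`` (zone 1 at x=0)."""
        if zone == 1:
            return x
        if zone == 2:
            return self.length - np.asarray(x)
        raise ValueError(f"zone must be 1 or 2, got {zone}")

    def in_reward_zone(self, x, zone: int):
        d = self._wall_distance(x, zone)
        return d < self.reward_zone_depth

    def in_reset_zone(self, x, zone: int):
        d = self._wall_distance(x, zone)
        return (d >= self.reward_zone_depth) & (
            d < self.reward_zone_depth + self.reset_zone_depth
        )

    def beyond_far_reset_boundary(self, x, zone: int):
        """True where the position has reached the *other* side's reset zone."""
        other = 2 if zone == 1 else 1
        d = self._wall_distance(x, other)
        return d < self.reward_zone_depth + self.reset_zone_depth

    @property
    def trigger_depth(self) -> float:
        """Outer boundary of the reset zone, measured from the wall."""
        return self.reward_zone_depth + self.reset_zone_depth


@dataclass(frozen=True)
class AgentSpec:
    """How a synthetic fly chooses to return after a reward-zone visit.

    kind ``rl`` requires ``rl_params`` (an :class:`~flyforage.rlmodels.RLParams`);
    ``deterministic`` returns with probability ``response_prob`` only on
    rewarded trials; ``random`` returns with ``response_prob`` on every trial.
    """

    kind: str = "random"
    rl_params: Any = None
    response_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("rl", "deterministic", "random"):
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if not 0.0 <= self.response_prob <= 1.0:
            raise ValueError("response_prob must be in [0, 1]")
        if (self.kind == "rl") != (self.rl_params is not None):
            raise ValueError("rl_params must be given iff kind == 'rl'")


@dataclass
class RunConfig:
    """Top-level configuration for a full pipeline run."""

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    conditions: list[float] = field(
        default_factory=lambda: [0.0, 0.05, 0.15, 0.30, 0.45, 0.60]
    )
    n_flies: int = 10
    n_trials: int = 400
    agent: dict = field(default_factory=lambda: {"kind": "rl", "model": "FQ",
                                                 "alpha": 0.3, "beta": 6.0,
                                                 "bias": 0.3})
    session_duration_s: float = 300.0
    m_lags: int = 10
    min_trials: int = 50
    truncate_minutes: float = 30.0
    n_init: int = 100
    f1_threshold: float = 0.5
    seed: int = 0
    outdir: str = "flyforage_out"

    def validate(self) -> None:
        if self.n_flies < 1 or self.n_trials < 1:
            raise ValueError("n_flies and n_trials must be >= 1")
        for p in self.conditions:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"condition probability {p} outside [0, 1]")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a TOML file."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    arena = ArenaConfig(**raw.pop("arena", {}))
    cfg = RunConfig(arena=arena, **raw)
    cfg.validate()
    return cfg


# -- seeding ----------------------------------------------------------


def subseed(master_seed: int, *keys) -> np.random.SeedSequence:
    """Derive an independent seed stream from a master seed and string/int keys.

    Keys are hashed so that every (fly, stage, condition) combination gets a
    decoupled stream regardless of iteration order.
    """
    tokens = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(tokens))


def spawn_rng(master_seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng(subseed(master_seed, *keys))


def config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return d
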