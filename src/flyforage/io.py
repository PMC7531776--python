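"""CSV/JSON readers and writers for the pipeline's tabular interfaces."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import Trajectory
from .trials import ChoiceSequence, Trial

__all__ = [
    "write_trajectory_csv", "read_trajectory_csv",
    "write_stim_csv", "read_stim_csv",
    "write_choice_sequence_csv", "read_choice_sequence_csv",
    "write_trials_csv", "write_json",
]


def write_trajectory_csv(traj: Trajectory, path) -> None:
    pd.DataFrame({"time_s": traj.time, "x_mm": traj.x, "y_mm": traj.y}).to_csv(
        path, index=False)


def read_trajectory_csv(path, stim_events=None) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(time=df["time_s"].to_numpy(), x=df["x_mm"].to_numpy(),
                      y=df["y_mm"].to_numpy(),
                      stim_events=list(stim_events or []))


def write_stim_csv(stim_log, path) -> None:
    pd.DataFrame(stim_log, columns=["time_s", "zone"]).to_csv(path, index=False)


def read_stim_csv(path) -> list[tuple[float, int]]:
    df = pd.read_csv(path)
    return [(float(t), int(z)) for t, z in zip(df["time_s"], df["zone"])]


def write_choice_sequence_csv(seq: ChoiceSequence, path) -> None:
    seq.to_frame().to_csv(path, index=False)


def read_choice_sequence_csv(path, **kw) -> ChoiceSequence:
    df = pd.read_csv(path)
    return ChoiceSequence(
        rewards=df["reward"].to_numpy(), choices=df["choice"].to_numpy(),
        zone=df["zone"].to_numpy() if "zone" in df else None,
        t_reward=df["t_reward_s"].to_numpy() if "t_reward_s" in df else None,
        **kw)


def write_trials_csv(trials: list[Trial], path, fly_id=None) -> None:
    pd.DataFrame([{
        "fly": fly_id, "trial": tr.index, "zone": tr.zone,
        "t_enter_reset": tr.t_enter_reset, "t_enter_reward": tr.t_enter_reward,
        "t_end": tr.t_end, "reward": tr.rewarded, "return": tr.returned,
        "max_excursion_x": tr.max_excursion_x,
    } for tr in trials]).to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder,
                                     sort_keys=True))
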