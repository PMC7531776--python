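"""Trajectory preprocessing and kinematic observables.

Observables follow the one-dimensional reading of the linear track:
stops are samples with speed at or below a small threshold, turns are
sign changes of the x-velocity, occupancy is the time-weighted histogram
of x, and path curvature is summarised by the entropy of the per-step
heading-angle distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "Trajectory",
    "KinematicsSummary",
    "StopInterval",
    "TurnEvent",
    "preprocess_trajectory",
    "detect_stops",
    "detect_turns",
    "occupancy_distribution",
    "preference_index",
    "heading_angles",
    "entropy_of_angles",
    "angular_distribution_entropy",
    "summarize",
]

STOP_SPEED_THRESHOLD = 0.01  # mm/s; one-pixel resolution of the tracker


@dataclass
class Trajectory:
    """Time-stamped planar positions with an optional stimulation log."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    stim_events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.time) == len(self.x) == len(self.y)):
            raise ValueError("time, x and y must have equal length")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def vx(self) -> np.ndarray:
        return np.gradient(self.x, self.time)

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(np.gradient(self.x, self.time),
                        np.gradient(self.y, self.time))


@dataclass(frozen=True)
class StopInterval:
    t_start: float
    t_end: float
    mean_x: float


@dataclass(frozen=True)
class TurnEvent:
    time: float
    x: float


@dataclass
class KinematicsSummary:
    occupancy: np.ndarray
    occupancy_edges: np.ndarray
    preference_index: float
    stop_histogram: np.ndarray
    turn_histogram: np.ndarray
    speed_histogram: np.ndarray
    speed_edges: np.ndarray
    angular_entropy: dict


def _interpolate_gaps(t: np.ndarray, v: np.ndarray) -> np.ndarray:
    ok = np.isfinite(v)
    if not ok.any():
        raise ValueError("trajectory contains no valid samples")
    if ok.all():
        return v
    return np.interp(t, t[ok], v[ok])


def preprocess_trajectory(
    raw: Trajectory,
    cutoff: float = 5.0,
    order: int = 2,
    jump_threshold: float | None = 5.0,
) -> Trajectory:
    """Clean and low-pass filter a raw trajectory.

    Missing samples (NaNs) are linearly interpolated; implausible jumps —
    inter-sample displacements larger than ``jump_threshold`` mm — are
    removed and re-interpolated; finally a zero-phase Butterworth low-pass
    filter (``order``, ``cutoff`` Hz) is applied to x and y.
    """
    if len(raw) < 2:
        raise ValueError("need at least 2 samples")
    t = np.asarray(raw.time, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    x = _interpolate_gaps(t, np.asarray(raw.x, dtype=float))
    y = _interpolate_gaps(t, np.asarray(raw.y, dtype=float))

    if jump_threshold is not None:
        disp = np.hypot(np.diff(x), np.diff(y))
        bad = np.flatnonzero(disp > jump_threshold) + 1
        if bad.size:
            x[bad] = np.nan
            y[bad] = np.nan
            x = _interpolate_gaps(t, x)
            y = _interpolate_gaps(t, y)

    fs = 1.0 / float(np.median(np.diff(t)))
    if cutoff is not None and cutoff < fs / 2 and len(t) > 3 * (order + 1):
        sos = signal.butter(order, cutoff, fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, x)
        y = signal.sosfiltfilt(sos, y)
    return Trajectory(time=t, x=x, y=y, stim_events=list(raw.stim_events))


def detect_stops(
    traj: Trajectory, threshold: float = STOP_SPEED_THRESHOLD
) -> list[StopInterval]:
    """Maximal intervals with speed ``|v| <= threshold``."""
    slow = traj.speed <= threshold
    out = []
    for i0, i1 in _runs(slow):
        out.append(StopInterval(
            t_start=float(traj.time[i0]),
            t_end=float(traj.time[i1]),
            mean_x=float(np.mean(traj.x[i0:i1 + 1])),
        ))
    return out


def _runs(mask: np.ndarray):
    """(first, last) index pairs of maximal True runs."""
    m = np.asarray(mask, bool)
    if not m.any():
        return
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if m[0]:
        starts = np.concatenate(([0], starts))
    if m[-1]:
        ends = np.concatenate((ends, [len(m) - 1]))
    yield from zip(starts, ends)


def detect_turns(traj: Trajectory, zero_tol: float = 1e-9) -> list[TurnEvent]:
    """Velocity-sign-change events of the x-component.

    Velocity is the forward difference, so the count equals the number of
    sign alternations in the displacement sequence.  Runs of (near-)zero
    velocity between opposite-sign segments count as exactly one turn;
    between same-sign segments they count as none.
    """
    vx = np.diff(traj.x) / np.diff(traj.time)
    s = np.sign(vx)
    s[np.abs(vx) <= zero_tol] = 0
    events = []
    last_sign = 0
    for i, si in enumerate(s):
        if si == 0:
            continue
        if last_sign != 0 and si != last_sign:
            # the step i -> i+1 moves in the new direction
            events.append(TurnEvent(time=float(traj.time[i]), x=float(traj.x[i])))
        last_sign = si
    return events


def occupancy_distribution(
    traj: Trajectory, n_bins: int = 50, length: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Time-weighted, normalised histogram of x over the arena length."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    t = traj.time
    dt = np.empty_like(t)
    dt[:-1] = np.diff(t)
    dt[-1] = dt[-2] if len(t) > 1 else 1.0
    if length is None:
        length = float(np.max(traj.x)) or 1.0
    hist, edges = np.histogram(traj.x, bins=n_bins, range=(0.0, length), weights=dt)
    total = hist.sum()
    if total <= 0:
        raise ValueError("no occupancy mass inside the arena range")
    return hist / total, edges


def preference_index(occ_zone1: float, occ_zone2: float) -> float:
    """(Z1 - Z2) / (Z1 + Z2): +1 exclusive zone-1 dwell, -1 zone 2, 0 neither."""
    if occ_zone1 < 0 or occ_zone2 < 0:
        raise ValueError("occupancies must be non-negative")
    total = occ_zone1 + occ_zone2
    if total <= 0:
        raise ValueError("undefined preference index: fly never visited either zone")
    return (occ_zone1 - occ_zone2) / total


def heading_angles(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-step heading angles of a path, referenced to one travel direction.

    Headings are the arctangent of consecutive displacements; whenever the
    travel orientation (sign of dx) flips, angles are shifted by pi so
    that every step is measured against one common reference direction.
    Zero-displacement steps are skipped.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need >= 2 samples of equal length")
    dx = np.diff(x)
    dy = np.diff(y)
    moving = np.hypot(dx, dy) > 0
    if not moving.any():
        raise ValueError("undefined entropy: path contains no displacement")
    dx, dy = dx[moving], dy[moving]
    ang = np.arctan2(dy, dx)
    # reference orientation = direction of travel of the first step
    orient = np.sign(dx)
    orient[orient == 0] = 1.0
    flipped = orient != orient[0]
    ang = np.where(flipped, ang + np.pi, ang)
    return np.mod(ang + np.pi, 2 * np.pi) - np.pi  # wrap to [-pi, pi)


def entropy_of_angles(
    angles: np.ndarray, n_angle_bins: int = 36, units: str = "nats"
) -> float:
    """Entropy S = -sum q_k log q_k of the normalised angle histogram.

    Bins are left-closed over [-pi, pi).  A point mass gives 0; a uniform
    histogram gives log(n_angle_bins).
    """
    if n_angle_bins < 1:
        raise ValueError("n_angle_bins must be >= 1")
    hist, _ = np.histogram(angles, bins=n_angle_bins, range=(-np.pi, np.pi))
    if hist.sum() == 0:
        raise ValueError("no angles to bin")
    q = hist[hist > 0] / hist.sum()
    s = float(-(q * np.log(q)).sum())
    if units == "bits":
        s /= np.log(2.0)
    elif units != "nats":
        raise ValueError("units must be 'nats' or 'bits'")
    return s


def angular_distribution_entropy(
    x: np.ndarray,
    y: np.ndarray,
    n_angle_bins: int = 36,
    units: str = "nats",
) -> float:
    """Entropy of the per-step heading-angle histogram of a path.

    A perfectly straight path gives 0; broader (more curved) paths give
    larger values, up to log(n_angle_bins) for a uniform histogram.
    """
    return entropy_of_angles(heading_angles(x, y), n_angle_bins, units)


def summarize(
    traj: Trajectory,
    config,
    n_bins: int = 50,
    n_angle_bins: int = 36,
    n_speed_bins: int = 30,
    units: str = "nats",
) -> KinematicsSummary:
    """Bundle the standard per-session observables.

    ``config`` is an :class:`~flyforage.config.ArenaConfig`; zone dwell
    times for the preference index are measured within the reset-zone
    (trigger) boundaries at each end.
    """
    occ, edges = occupancy_distribution(traj, n_bins=n_bins, length=config.length)
    dt = np.empty_like(traj.time)
    dt[:-1] = np.diff(traj.time)
    dt[-1] = dt[-2]
    depth = config.trigger_depth
    dwell1 = float(dt[traj.x < depth].sum())
    dwell2 = float(dt[traj.x > config.length - depth].sum())
    try:
        pi = preference_index(dwell1, dwell2)
    except ValueError:
        pi = float("nan")

    stop_hist = np.histogram(
        [s.mean_x for s in detect_stops(traj)], bins=n_bins, range=(0, config.length)
    )[0]
    turn_hist = np.histogram(
        [e.x for e in detect_turns(traj)], bins=n_bins, range=(0, config.length)
    )[0]
    sp = traj.speed
    speed_hist, speed_edges = np.histogram(sp, bins=n_speed_bins)

    entropy = {"whole_path": angular_distribution_entropy(
        traj.x, traj.y, n_angle_bins=n_angle_bins, units=units)}
    return KinematicsSummary(
        occupancy=occ, occupancy_edges=edges, preference_index=pi,
        stop_histogram=stop_hist, turn_histogram=turn_hist,
        speed_histogram=speed_hist, speed_edges=speed_edges,
        angular_entropy=entropy,
    )
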