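"""Kinematic features from speed and acceleration telemetry.

Sliding-window averages capture the local driving regime; the window
standard deviation of speed captures how actively the driver regulates it
(hypnotic driving is steadier); jerk — the point-by-point derivative of
acceleration — captures abrupt corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeline_io import SampledSignal

__all__ = ["KinematicFeatures", "sliding_mean", "sliding_std", "jerk",
           "kinematic_features", "KMH_TO_MS"]

#: km/h → m/s conversion for telemetry that arrives in km/h
KMH_TO_MS = 1.0 / 3.6


def _window_slices(n: int, rate: float, t_w: float, step: float):
    win = max(int(round(t_w * rate)), 1)
    hop = max(int(round(step * rate)), 1)
    starts = range(0, max(n - win, 0) + 1, hop)
    return [(s, s + win) for s in starts], win, hop


def sliding_mean(series: np.ndarray, rate: float, t_w: float,
                 step: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean over each window ``[t_i, t_i + T_w)``; returns (start indices, means)."""
    x = np.asarray(series, dtype=float)
    slices, win, _ = _window_slices(len(x), rate, t_w, step)
    if not slices:
        raise ValueError("window longer than series")
    starts = np.array([s for s, _ in slices])
    means = np.array([x[s:e].mean() for s, e in slices])
    return starts, means


def sliding_std(series: np.ndarray, rate: float, t_w: float,
                step: float) -> tuple[np.ndarray, np.ndarray]:
    """Population standard deviation (divisor N) over each window."""
    x = np.asarray(series, dtype=float)
    slices, win, _ = _window_slices(len(x), rate, t_w, step)
    if not slices:
        raise ValueError("window longer than series")
    starts = np.array([s for s, _ in slices])
    stds = np.array([x[s:e].std(ddof=0) for s, e in slices])
    return starts, stds


def jerk(acceleration: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Forward difference ``(a[i+1] − a[i]) / (t[i+1] − t[i])``, length n−1."""
    a = np.asarray(acceleration, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(a) < 2:
        raise ValueError("need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    return np.diff(a) / dt


@dataclass
class KinematicFeatures:
    """Windowed kinematics plus per-sample jerk."""

    window_starts: np.ndarray  # s, on the reference clock
    avg_speed: np.ndarray  # m/s
    std_speed: np.ndarray  # m/s
    avg_acceleration: np.ndarray  # m/s²
    jerk_times: np.ndarray  # s
    jerk: np.ndarray  # m/s³
    window_length: float  # s


def kinematic_features(vehicle: SampledSignal, t_w: float = 5.0,
                       step: float = 1.0,
                       speed_in_kmh: bool = False) -> KinematicFeatures:
    """Full kinematic feature set from a vehicle telemetry stream."""
    speed = vehicle.channel("speed") * (KMH_TO_MS if speed_in_kmh else 1.0)
    accel = vehicle.channel("acceleration")
    rate = vehicle.sampling_rate
    starts, avg_v = sliding_mean(speed, rate, t_w, step)
    _, std_v = sliding_std(speed, rate, t_w, step)
    _, avg_a = sliding_mean(accel, rate, t_w, step)
    times = vehicle.times
    j = jerk(accel, times)
    return KinematicFeatures(
        window_starts=vehicle.start_time + starts / rate,
        avg_speed=avg_v,
        std_speed=std_v,
        avg_acceleration=avg_a,
        jerk_times=times[:-1],
        jerk=j,
        window_length=t_w,
    )
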