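"""Synthetic multimodal driving sessions with a latent two-state Markov chain.

Real recordings of road hypnosis are private clinical-style data, so the
toolkit ships a generator that reproduces the *statistical structure* the
analysis assumes: a slow latent state (normal vs. hypnosis) switching at
1 Hz modulates (i) the variance of band-limited EEG components, (ii) the
level and fluctuation of the eye channels, and (iii) how steadily speed is
held.  Hypnotic driving raises slow-wave (delta/theta) EEG power, lowers
beta power, damps pupil fluctuations, and smooths speed — directions chosen
as plausible drowsiness-like defaults; they are configuration, not claims
about any particular dataset.  The beta-band effect is the designed
dominant feature.

Everything is deterministic given the master seed; sub-seeds are drawn per
session and per modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .eeg_features import DEFAULT_BANDS
from .timeline_io import (EYE_CHANNELS, EventIntervals, HYPNOSIS,
                          MultimodalRecording, NORMAL, SampledSignal,
                          VEHICLE_CHANNELS, write_recording)

__all__ = ["SimConfig", "simulate_latent_path", "synthesize_eeg",
           "synthesize_eye", "synthesize_vehicle", "simulate_recording",
           "generate_dataset"]

STATE_NORMAL, STATE_HYPNOSIS = 0, 1


@dataclass
class SimConfig:
    """Study-condition defaults for the generator.

    The latent chain runs at 1 Hz with the hypnosis state in the minority
    (stationary occupancy 1/3).  Per-state emission parameters follow the
    qualitative structure above; sampling rates are 500 Hz (EEG, 4
    channels), 100 Hz (eye) and 10 Hz (vehicle).
    """

    duration: float = 300.0  # s per session
    seed: int = 0
    n_recordings: int = 26
    # latent chain at 1 Hz
    initial: tuple[float, float] = (1.0, 0.0)  # sessions start in normal driving
    transitions: tuple[tuple[float, float], tuple[float, float]] = (
        (0.95, 0.05), (0.10, 0.90))
    # sampling rates
    eeg_rate: float = 500.0
    eye_rate: float = 100.0
    vehicle_rate: float = 10.0
    n_eeg_channels: int = 4
    # EEG band component sds (signal units) per state [normal, hypnosis];
    # hypnosis: delta/theta x1.5, beta x0.6 (beta is the dominant effect)
    band_sd_normal: tuple[float, ...] = (8.0, 6.0, 5.0, 5.0, 3.0)
    band_sd_hypnosis: tuple[float, ...] = (12.0, 9.0, 5.0, 3.0, 3.0)
    # eye channels: mean / fluctuation-sd per state
    pupil_mean: tuple[float, float] = (4.0, 4.4)  # mm
    pupil_sd: tuple[float, float] = (0.35, 0.12)  # mm; hypnosis: damped
    gaze_velocity_mean: tuple[float, float] = (60.0, 25.0)  # deg/s
    gaze_velocity_sd: tuple[float, float] = (25.0, 10.0)
    ipd_mean: tuple[float, float] = (62.0, 62.0)  # mm, near-constant
    ipd_sd: tuple[float, float] = (0.05, 0.05)
    invalid_rate: float = 0.01  # blink/dropout injection probability
    # vehicle
    speed_mean: tuple[float, float] = (13.0, 14.0)  # m/s
    speed_sd: tuple[float, float] = (1.5, 0.4)  # hypnosis: steadier
    ar_coefficient: float = 0.95  # slow physiological / behavioural drift

    def validate(self) -> None:
        a = np.asarray(self.transitions, dtype=float)
        if a.shape != (2, 2) or np.any(a < 0) or np.max(np.abs(a.sum(1) - 1)) > 1e-9:
            raise ValueError("transitions must be a 2x2 stochastic matrix")
        for name in ("band_sd_normal", "band_sd_hypnosis", "pupil_sd",
                     "gaze_velocity_sd", "ipd_sd", "speed_sd"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-negative")
        for name in ("eeg_rate", "eye_rate", "vehicle_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def simulate_latent_path(initial, transitions, n_steps: int, seed: int
                         ) -> tuple[np.ndarray, EventIntervals]:
    """Sample the 1 Hz latent chain; intervals are maximal hypnosis runs."""
    pi = np.asarray(initial, dtype=float)
    a = np.asarray(transitions, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or np.any(a < 0) \
            or np.max(np.abs(a.sum(axis=1) - 1)) > 1e-9:
        raise ValueError("invalid transition matrix")
    rng = np.random.default_rng(seed)
    states = np.empty(n_steps, dtype=int)
    states[0] = rng.choice(len(pi), p=pi)
    for t in range(1, n_steps):
        states[t] = rng.choice(len(pi), p=a[states[t - 1]])
    intervals = []
    in_run, run_start = False, 0
    for t, s in enumerate(states):
        if s == STATE_HYPNOSIS and not in_run:
            in_run, run_start = True, t
        elif s != STATE_HYPNOSIS and in_run:
            intervals.append((float(run_start), float(t), HYPNOSIS))
            in_run = False
    if in_run:
        intervals.append((float(run_start), float(n_steps), HYPNOSIS))
    return states, EventIntervals(intervals)


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Unit-variance stationary AR(1) noise."""
    from scipy.signal import lfilter

    innov = rng.normal(size=n) * np.sqrt(1 - phi**2)
    innov[0] = rng.normal()  # stationary start
    return lfilter([1.0], [1.0, -phi], innov)


def _per_sample(states: np.ndarray, rate: float) -> np.ndarray:
    """Expand the 1 Hz state sequence to one value per sample."""
    reps = int(round(rate))
    return np.repeat(states, reps)


def synthesize_eeg(states: np.ndarray, config: SimConfig, seed: int
                   ) -> SampledSignal:
    """State-modulated sum of five band-limited Gaussian components.

    Each band component is white noise brick-wall-filtered into its band
    over the whole record, normalized to unit variance, then amplitude-
    modulated by the state-dependent band standard deviation of each 1-s
    state step.  (Whole-record filtering avoids block-boundary artifacts;
    the per-step band variance structure is identical to filtering each
    block separately.)
    """
    config.validate()
    from .eeg_features import bandpass_fft  # local import: avoid cycle at import time

    rng = np.random.default_rng(seed)
    n = int(round(len(states) * config.eeg_rate))
    sd_table = np.stack([config.band_sd_normal, config.band_sd_hypnosis])
    sample_states = _per_sample(states, config.eeg_rate)
    values = np.zeros((n, config.n_eeg_channels))
    for ch in range(config.n_eeg_channels):
        total = np.zeros(n)
        for k, band in enumerate(DEFAULT_BANDS):
            white = SampledSignal(["w"], config.eeg_rate, 0.0,
                                  rng.normal(size=(n, 1)))
            component = bandpass_fft(white, band.f1, band.f2).values[:, 0]
            sd = component.std()
            if sd > 0:
                component /= sd
            total += component * sd_table[sample_states, k]
        values[:, ch] = total
    return SampledSignal(
        channel_names=[f"eeg_{i + 1}" for i in range(config.n_eeg_channels)],
        sampling_rate=config.eeg_rate, start_time=0.0, values=values)


def synthesize_eye(states: np.ndarray, config: SimConfig, seed: int
                   ) -> SampledSignal:
    """Pupil / gaze / IPD channels with state-dependent level and variance.

    Pupils: state mean + AR(1) fluctuation with state-dependent sd (damped
    in hypnosis).  Gaze velocity: rectified Gaussian around a state mean.
    IPD: near-constant.  A configurable fraction of samples is zeroed and
    flagged invalid to exercise the cleaning stage.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = int(round(len(states) * config.eye_rate))
    s = _per_sample(states, config.eye_rate)
    phi = config.ar_coefficient

    def level_noise(mean_pair, sd_pair):
        return (np.asarray(mean_pair)[s]
                + _ar1(rng, n, phi) * np.asarray(sd_pair)[s])

    pupil_l = level_noise(config.pupil_mean, config.pupil_sd)
    pupil_r = level_noise(config.pupil_mean, config.pupil_sd)
    gaze = np.abs(np.asarray(config.gaze_velocity_mean)[s]
                  + _ar1(rng, n, phi) * np.asarray(config.gaze_velocity_sd)[s])
    ipd = level_noise(config.ipd_mean, config.ipd_sd)
    valid = (rng.random(n) >= config.invalid_rate).astype(float)
    bad = valid == 0
    for col in (pupil_l, pupil_r, gaze):
        col[bad] = 0.0  # dropout looks like lost tracking
    values = np.column_stack([pupil_l, pupil_r, gaze, ipd, valid])
    return SampledSignal(channel_names=list(EYE_CHANNELS),
                         sampling_rate=config.eye_rate, start_time=0.0,
                         values=values)


def synthesize_vehicle(states: np.ndarray, config: SimConfig, seed: int
                       ) -> SampledSignal:
    """Speed with state-dependent steadiness; acceleration by construction.

    Acceleration is the exact finite difference of speed (divided by the
    sample period), so jerk computed downstream equals the second difference
    of speed — the modalities are self-consistent.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = int(round(len(states) * config.vehicle_rate))
    s = _per_sample(states, config.vehicle_rate)
    speed = (np.asarray(config.speed_mean)[s]
             + _ar1(rng, n, config.ar_coefficient) * np.asarray(config.speed_sd)[s])
    dt = 1.0 / config.vehicle_rate
    acceleration = np.empty(n)
    acceleration[:-1] = np.diff(speed) / dt
    acceleration[-1] = acceleration[-2] if n > 1 else 0.0
    return SampledSignal(channel_names=list(VEHICLE_CHANNELS),
                         sampling_rate=config.vehicle_rate, start_time=0.0,
                         values=np.column_stack([speed, acceleration]))


def simulate_recording(config: SimConfig, seed: int,
                       name: str = "session") -> MultimodalRecording:
    """One full synthetic session (all modalities share one latent path)."""
    config.validate()
    root = np.random.default_rng(seed)
    sub = root.integers(0, 2**31 - 1, size=4)
    n_steps = int(round(config.duration))
    states, intervals = simulate_latent_path(
        config.initial, config.transitions, n_steps, int(sub[0]))
    return MultimodalRecording(
        eeg=synthesize_eeg(states, config, int(sub[1])),
        eye=synthesize_eye(states, config, int(sub[2])),
        vehicle=synthesize_vehicle(states, config, int(sub[3])),
        labels=intervals,
        name=name,
    )


def generate_dataset(config: SimConfig | None = None,
                     out_dir: Path | str | None = None
                     ) -> list[MultimodalRecording]:
    """``n_recordings`` independent sessions with distinct sub-seeds.

    When ``out_dir`` is given, each session is written as a directory of
    the standard CSV dialects.
    """
    cfg = config or SimConfig()
    cfg.validate()
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(0, 2**31 - 1, size=max(cfg.n_recordings, 1))
    recordings = []
    for i in range(cfg.n_recordings):
        rec = simulate_recording(cfg, int(seeds[i]), name=f"session_{i:02d}")
        if out_dir is not None:
            write_recording(rec, Path(out_dir) / rec.name)
        recordings.append(rec)
    return recordings
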