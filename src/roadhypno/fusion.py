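"""Feature standardization, cross-modality alignment, and the fused
observation matrix.

Modalities arrive at very different native rates (EEG band power near the
EEG rate, eye channels at 100 Hz, vehicle kinematics near 1 Hz).  Each
feature stream is averaged onto a common uniform grid (1 Hz by default) over
a short alignment window, z-scored with training-set moments, and assembled
into the observation matrix the decoder consumes.  Rows are labelled from
the annotated state intervals; unlabelled time is normal driving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import eeg_features, eye_features, vehicle_features
from .config import RunConfig
from .timeline_io import EventIntervals, HYPNOSIS, MultimodalRecording, NORMAL, synchronize

logger = logging.getLogger(__name__)

#: fixed fused-feature order; serialized with every trained model
DEFAULT_FEATURE_ORDER = [
    "speed",
    "acceleration",
    "delta",
    "theta",
    "alpha",
    "beta",
    "gamma",
    "gaze_velocity",
    "pupil_diameter_left",
    "pupil_diameter_right",
    "ipd",
]

#: 14-slot layout of the linear hypnosis-degree readout.  Slots 2, 3, 11 and
#: 13 are reserved padding (their coefficients are zero); the remaining ten
#: carry the named fused features.
SLOT_FEATURES: list[str | None] = [
    "speed",  # slot 1
    None,  # slot 2 (reserved)
    None,  # slot 3 (reserved)
    "delta",  # slot 4
    "theta",  # slot 5
    "alpha",  # slot 6
    "beta",  # slot 7
    "gamma",  # slot 8
    "gaze_velocity",  # slot 9
    "pupil_diameter_left",  # slot 10
    None,  # slot 11 (reserved)
    "pupil_diameter_right",  # slot 12
    None,  # slot 13 (reserved)
    "ipd",  # slot 14
]

STATES = [NORMAL, HYPNOSIS]


@dataclass
class FeatureMatrix:
    """Time-indexed fused feature vectors (the observation sequence).

    ``data`` holds one row per grid time in a fixed column order; ``labels``
    (optional) holds one state name per row.  ``mean``/``std`` are the
    population standardization moments; they are set once the matrix has
    been z-scored and travel with the trained model so that inference
    applies the training-set moments unchanged.
    """

    times: np.ndarray
    data: pd.DataFrame
    labels: np.ndarray | None = None
    mean: dict[str, float] | None = None
    std: dict[str, float] | None = None
    recording: str = "recording"

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def to_slots(self) -> np.ndarray:
        """Map rows onto the 14-slot readout layout (padding slots = 0)."""
        out = np.zeros((len(self), len(SLOT_FEATURES)))
        for j, name in enumerate(SLOT_FEATURES):
            if name is not None and name in self.data.columns:
                out[:, j] = self.data[name].to_numpy()
        return out


def standardize(matrix: FeatureMatrix,
                params: tuple[dict, dict] | None = None) -> FeatureMatrix:
    """Z-score every column: ``(f − μ) / σ`` with population moments.

    Without ``params`` the moments are estimated from the matrix itself
    (training); with ``params = (mean, std)`` they are applied unchanged
    (inference).  A zero-variance column without supplied params is an
    error.
    """
    if params is None:
        mean = {c: float(matrix.data[c].mean()) for c in matrix.columns}
        std = {c: float(matrix.data[c].std(ddof=0)) for c in matrix.columns}
        dead = [c for c, s in std.items() if s == 0]
        if dead:
            raise ValueError(f"zero-variance column(s): {dead}")
    else:
        mean, std = params
    data = (matrix.data - pd.Series(mean)) / pd.Series(std)
    return FeatureMatrix(
        times=matrix.times,
        data=data[matrix.columns],
        labels=matrix.labels,
        mean=mean,
        std=std,
        recording=matrix.recording,
    )


def align(streams: dict[str, tuple[np.ndarray, np.ndarray]],
          t_window: float = 1.0, grid_rate: float = 1.0,
          columns: list[str] | None = None) -> FeatureMatrix:
    """Average native-rate feature streams onto a common uniform grid.

    ``streams`` maps a feature name to ``(times, values)`` at its native
    rate.  A grid row at time ``t`` holds, per feature, the mean of its
    samples in the half-open window ``[t, t + t_window)``.  Grid rows where
    any feature's window is empty are dropped (and counted in the log).
    """
    if not streams:
        raise ValueError("no feature streams")
    t_lo = max(float(np.min(t)) for t, _ in streams.values())
    t_hi = min(float(np.max(t)) for t, _ in streams.values())
    if not t_lo < t_hi:
        raise ValueError("feature streams have no common time span")
    dt = 1.0 / grid_rate
    first = np.ceil(round(t_lo / dt, 9)) * dt
    grid = np.arange(first, t_hi + 1e-9, dt)
    if grid.size == 0:
        raise ValueError("empty alignment grid")
    names = columns if columns is not None else list(streams)
    out = np.empty((grid.size, len(names)))
    valid = np.ones(grid.size, dtype=bool)
    for j, name in enumerate(names):
        t, v = streams[name]
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        order = np.argsort(t, kind="stable")
        t, v = t[order], v[order]
        csum = np.concatenate([[0.0], np.cumsum(v)])
        # half-open [t_k, t_k + T): left edge inclusive, right edge exclusive
        i0 = np.searchsorted(t, grid - 1e-9, side="right")
        i1 = np.searchsorted(t, grid + t_window - 1e-9, side="right")
        counts = i1 - i0
        with np.errstate(invalid="ignore"):
            out[:, j] = np.where(counts > 0, (csum[i1] - csum[i0]) / np.maximum(counts, 1),
                                 np.nan)
        valid &= counts > 0
    dropped = int((~valid).sum())
    if dropped:
        logger.info("align: dropped %d grid rows with empty windows", dropped)
    return FeatureMatrix(times=grid[valid], data=pd.DataFrame(out[valid], columns=names))


def label_rows(matrix: FeatureMatrix, intervals: EventIntervals) -> FeatureMatrix:
    """Attach a state label per grid row; unlabelled time is normal driving."""
    labels = intervals.label_at(matrix.times, labels=[HYPNOSIS], default=NORMAL)
    return FeatureMatrix(
        times=matrix.times,
        data=matrix.data,
        labels=labels,
        mean=matrix.mean,
        std=matrix.std,
        recording=matrix.recording,
    )


def extract_features(recording: MultimodalRecording,
                     config: RunConfig | None = None) -> FeatureMatrix:
    """Run all three modality extractors and fuse onto the common grid.

    The result is labelled but *not* standardized; standardization moments
    must come from the training set (see :func:`standardize`).
    """
    cfg = config or RunConfig()
    rec = synchronize(recording)

    # --- EEG: drop -> average reference -> band-pass -> sliding band power
    eeg = rec.eeg
    if cfg.eeg.drop:
        eeg = eeg_features.drop_channels(eeg, cfg.eeg.drop)
    if cfg.eeg.average_ref and eeg.n_channels >= 2:
        eeg = eeg_features.average_reference(eeg)
    eeg = eeg_features.bandpass_fft(eeg, cfg.eeg.low_cut, cfg.eeg.high_cut)
    step = max(int(round(cfg.eeg.step_s * eeg.sampling_rate)), 1)
    bp = eeg_features.sliding_band_power(eeg, cfg.eeg.window_s, step)
    band_values = bp.values.mean(axis=2) if cfg.eeg.channel_mean else bp.values[..., 0]

    # --- eye: clean -> low-pass -> high-pass -> moving average
    eye = eye_features.clean_eye(rec.eye)
    data_channels = [c for c in eye.channel_names if c != "valid"]
    eye = eeg_features.drop_channels(eye, [c for c in eye.channel_names
                                           if c not in data_channels])
    lp = eye_features.design_fir(cfg.eye.fc_low, eye.sampling_rate,
                                 cfg.eye.order_low, "lowpass")
    hp = eye_features.design_fir(cfg.eye.fc_high, eye.sampling_rate,
                                 cfg.eye.order_high, "highpass")
    eye = eye_features.apply_fir(eye, lp)
    eye = eye_features.apply_fir(eye, hp)
    eye = eye_features.moving_average(eye, cfg.eye.ma_window)

    # --- vehicle: sliding kinematics
    kin = vehicle_features.kinematic_features(
        rec.vehicle, cfg.vehicle.window_s, cfg.vehicle.step_s,
        speed_in_kmh=cfg.vehicle.speed_in_kmh)

    streams: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "speed": (kin.window_starts, kin.avg_speed),
        "acceleration": (kin.window_starts, kin.avg_acceleration),
    }
    for k, band in enumerate(bp.band_names):
        streams[band] = (bp.times, band_values[:, k])
    for name in data_channels:
        streams[name] = (eye.times, eye.channel(name))

    columns = [c for c in DEFAULT_FEATURE_ORDER if c in streams]
    matrix = align(streams, cfg.fusion.t_window, cfg.fusion.grid_rate,
                   columns=columns)

    if cfg.eye.use_lle:
        emb = eye_features.lle_embed(
            matrix.data[data_channels].to_numpy(),
            n_neighbors=cfg.eye.lle_k, n_components=cfg.eye.lle_d)
        for d in range(emb.coordinates.shape[1]):
            matrix.data[f"lle_{d + 1}"] = emb.coordinates[:, d]

    matrix.recording = rec.name
    matrix = label_rows(matrix, rec.labels)
    counts = pd.Series(matrix.labels).value_counts().to_dict()
    logger.info("fused %s: %d rows, class counts %s", rec.name, len(matrix), counts)
    return matrix


def concat_matrices(matrices: list[FeatureMatrix]) -> FeatureMatrix:
    """Stack several recordings' fused matrices into one training table."""
    if not matrices:
        raise ValueError("no matrices to concatenate")
    cols = matrices[0].columns
    for m in matrices[1:]:
        if m.columns != cols:
            raise ValueError("feature columns differ across matrices")
    return FeatureMatrix(
        times=np.concatenate([m.times for m in matrices]),
        data=pd.concat([m.data for m in matrices], ignore_index=True),
        labels=(np.concatenate([m.labels for m in matrices])
                if all(m.labels is not None for m in matrices) else None),
        recording="+".join(m.recording for m in matrices),
    )
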