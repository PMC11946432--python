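"""Synchronized multimodal recordings and their delimited-text formats.

A recording bundles three regularly sampled streams (EEG, eye tracking,
vehicle telemetry) expressed on one reference clock, plus labelled state
intervals.  Sample ``i`` of a stream covers the half-open instant
``start_time + i / sampling_rate``; intervals are half-open
``[t_start, t_end)`` so adjacent intervals never double-count a sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical channel layouts for the three modalities
EYE_CHANNELS = [
    "pupil_diameter_left",
    "pupil_diameter_right",
    "gaze_velocity",
    "ipd",
    "valid",
]
VEHICLE_CHANNELS = ["speed", "acceleration"]

NORMAL = "normal"
HYPNOSIS = "hypnosis"


class SchemaError(ValueError):
    """A file or in-memory object violates the documented column schema."""


class FormatError(ValueError):
    """A file is structurally readable but semantically malformed."""


@dataclass
class SampledSignal:
    """A regularly sampled multichannel time series.

    Parameters
    ----------
    channel_names
        Unique identifier per column of ``values``.
    sampling_rate
        Samples per second, > 0.
    start_time
        Time of sample 0 on the shared reference clock, in seconds.
    values
        Array of shape ``(n_samples, n_channels)``.
    """

    channel_names: list[str]
    sampling_rate: float
    start_time: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise SchemaError("values must be 2-D [n_samples x n_channels]")
        if self.values.shape[1] != len(self.channel_names):
            raise SchemaError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise SchemaError(f"duplicate channel names in {self.channel_names}")
        if not self.sampling_rate > 0:
            raise SchemaError("sampling_rate must be > 0")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def end_time(self) -> float:
        """Time just past the last sample (exclusive span end)."""
        return self.start_time + self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
        return self.values[:, idx]

    def crop(self, t_start: float, t_end: float) -> "SampledSignal":
        """Restrict to samples whose time lies in ``[t_start, t_end)``."""
        i0 = int(np.ceil(round((t_start - self.start_time) * self.sampling_rate, 9)))
        i1 = int(np.ceil(round((t_end - self.start_time) * self.sampling_rate, 9)))
        i0 = max(i0, 0)
        i1 = min(max(i1, i0), self.n_samples)
        return SampledSignal(
            channel_names=list(self.channel_names),
            sampling_rate=self.sampling_rate,
            start_time=self.start_time + i0 / self.sampling_rate,
            values=self.values[i0:i1].copy(),
        )


@dataclass
class EventIntervals:
    """Labelled half-open time intervals ``[t_start, t_end)`` on the clock."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t0, t1, label in self.intervals:
            if not t0 < t1:
                raise FormatError(f"interval [{t0}, {t1}) for {label!r}: t_start >= t_end")
        by_label: dict[str, list[tuple[float, float]]] = {}
        for t0, t1, label in self.intervals:
            by_label.setdefault(label, []).append((t0, t1))
        for label, spans in by_label.items():
            spans.sort()
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                if b0 < a1:
                    raise FormatError(
                        f"overlapping {label!r} intervals [{a0},{a1}) and [{b0},{b1})"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def with_label(self, label: str) -> list[tuple[float, float]]:
        return sorted((t0, t1) for t0, t1, lab in self.intervals if lab == label)

    def clip(self, t_start: float, t_end: float) -> "EventIntervals":
        """Intersect every interval with ``[t_start, t_end)``; drop empties."""
        out = []
        for t0, t1, label in self.intervals:
            c0, c1 = max(t0, t_start), min(t1, t_end)
            if c0 < c1:
                out.append((c0, c1, label))
        return EventIntervals(out)

    def label_at(self, times: np.ndarray, labels: Sequence[str],
                 default: str = NORMAL) -> np.ndarray:
        """Label each time point; unlabelled time maps to ``default``."""
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, default, dtype=object)
        for t0, t1, label in self.intervals:
            if label in labels:
                out[(times >= t0) & (times < t1)] = label
        return out.astype(str)


@dataclass
class MultimodalRecording:
    """EEG + eye + vehicle streams with label intervals on one clock."""

    eeg: SampledSignal
    eye: SampledSignal
    vehicle: SampledSignal
    labels: EventIntervals
    name: str = "recording"

    @property
    def signals(self) -> Mapping[str, SampledSignal]:
        return {"eeg": self.eeg, "eye": self.eye, "vehicle": self.vehicle}


# ---------------------------------------------------------------------------
# synchronization & interval extraction


def synchronize(recording: MultimodalRecording) -> MultimodalRecording:
    """Crop all streams to their common time span; clip labels to it.

    Pure crop-to-overlap: no resampling, so sample values are bit-faithful.
    Idempotent.
    """
    t0 = max(s.start_time for s in recording.signals.values())
    t1 = min(s.end_time for s in recording.signals.values())
    if not t0 < t1:
        spans = {k: (s.start_time, s.end_time) for k, s in recording.signals.items()}
        raise FormatError(f"streams have no common time span: {spans}")
    return MultimodalRecording(
        eeg=recording.eeg.crop(t0, t1),
        eye=recording.eye.crop(t0, t1),
        vehicle=recording.vehicle.crop(t0, t1),
        labels=recording.labels.clip(t0, t1),
        name=recording.name,
    )


def extract_intervals(signal: SampledSignal, intervals: EventIntervals,
                      label: str) -> SampledSignal:
    """Concatenate, in time order, the signal restricted to ``label`` intervals.

    Returns an empty signal (not an error) when no interval carries the label.
    The concatenated signal keeps the first matching interval's start time;
    later segments follow back-to-back, so absolute times are not preserved
    past the first gap (the output is a new analysis object, not a crop).
    """
    spans = intervals.with_label(label)
    if not spans:
        logger.info("no %r intervals; returning empty signal", label)
        return replace(signal, values=signal.values[:0].copy())
    pieces = [signal.crop(t0, t1) for t0, t1 in spans]
    values = np.concatenate([p.values for p in pieces], axis=0)
    return replace(signal, start_time=pieces[0].start_time, values=values)


# ---------------------------------------------------------------------------
# CSV dialects
#
# eeg.csv:     time_s, <ch1>..<chN>
# eye.csv:     time_s, pupil_diameter_left, pupil_diameter_right,
#              gaze_velocity, ipd, valid
# vehicle.csv: time_s, speed, acceleration
# labels.csv:  t_start, t_end, label


def _read_signal_csv(path: Path | str, required: Sequence[str] | None = None
                     ) -> SampledSignal:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if len(set(header)) != len(header):
        raise SchemaError(f"{path}: duplicated channel name in header")
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise SchemaError(f"{path}: missing mandatory column 'time_s'")
    channels = [c for c in df.columns if c != "time_s"]
    if not channels:
        raise SchemaError(f"{path}: no data channels")
    if len(set(channels)) != len(channels):
        raise SchemaError(f"{path}: duplicated channel name")
    if required is not None:
        missing = [c for c in required if c not in channels]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    n_bad = int(df.isna().any(axis=1).sum())
    if n_bad:
        logger.warning("%s: dropped %d malformed rows", path, n_bad)
        df = df.dropna()
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples to infer the rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: non-monotone timestamps")
    step = np.median(dt)
    if np.max(np.abs(dt - step)) > 0.01 * step:
        raise FormatError(f"{path}: timestamps are not regularly spaced")
    return SampledSignal(
        channel_names=channels,
        sampling_rate=1.0 / step,
        start_time=float(t[0]),
        values=df[channels].to_numpy(dtype=float),
    )


def _read_labels_csv(path: Path | str) -> EventIntervals:
    df = pd.read_csv(path)
    for col in ("t_start", "t_end", "label"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    return EventIntervals(
        [(float(r.t_start), float(r.t_end), str(r.label)) for r in df.itertuples()]
    )


def read_recording(eeg_path, eye_path, vehicle_path, labels_path,
                   name: str | None = None) -> MultimodalRecording:
    """Read the four CSV files of one session into a recording."""
    return MultimodalRecording(
        eeg=_read_signal_csv(eeg_path),
        eye=_read_signal_csv(eye_path, required=EYE_CHANNELS),
        vehicle=_read_signal_csv(vehicle_path, required=VEHICLE_CHANNELS),
        labels=_read_labels_csv(labels_path),
        name=name or Path(eeg_path).parent.name,
    )


def read_session_dir(session_dir: Path | str) -> MultimodalRecording:
    """Read a session directory laid out as written by :func:`write_recording`."""
    d = Path(session_dir)
    return read_recording(
        d / "eeg.csv", d / "eye.csv", d / "vehicle.csv", d / "labels.csv",
        name=d.name,
    )


def _write_signal_csv(signal: SampledSignal, path: Path) -> None:
    df = pd.DataFrame(signal.values, columns=signal.channel_names)
    df.insert(0, "time_s", signal.times)
    df.to_csv(path, index=False, float_format="%.17g")


def write_recording(recording: MultimodalRecording, session_dir: Path | str) -> Path:
    """Write one session as eeg/eye/vehicle/labels CSVs under ``session_dir``."""
    d = Path(session_dir)
    d.mkdir(parents=True, exist_ok=True)
    _write_signal_csv(recording.eeg, d / "eeg.csv")
    _write_signal_csv(recording.eye, d / "eye.csv")
    _write_signal_csv(recording.vehicle, d / "vehicle.csv")
    pd.DataFrame(
        recording.labels.intervals, columns=["t_start", "t_end", "label"]
    ).to_csv(d / "labels.csv", index=False, float_format="%.17g")
    return d


def read_eeg_edf(path: Path | str) -> SampledSignal:
    """Optional EDF reader for EEG (requires the ``mne`` package)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF support requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return SampledSignal(
        channel_names=list(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        start_time=0.0,
        values=raw.get_data().T,
    )
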