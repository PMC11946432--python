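"""EEG preprocessing and sliding-window band-power features.

The EEG chain is: drop auxiliary channels, re-reference to the common
average, ideal (brick-wall FFT mask) band-pass filtering, then Welch
power-spectral-density estimation on short sliding windows with the power
integrated over the five canonical bands (delta through gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .timeline_io import SampledSignal

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "PsdEstimate",
    "BandPowerSeries",
    "bandpass_fft",
    "average_reference",
    "drop_channels",
    "welch_psd",
    "band_power",
    "sliding_band_power",
]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band ``[f1, f2)`` in Hz."""

    name: str
    f1: float
    f2: float

    def __post_init__(self) -> None:
        if not (0 <= self.f1 < self.f2):
            raise ValueError(f"band {self.name}: need 0 <= f1 < f2")


#: canonical scalp-rhythm bands
DEFAULT_BANDS = [
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 40.0),
]

BAND_NAMES = [b.name for b in DEFAULT_BANDS]


@dataclass
class PsdEstimate:
    """One-sided power spectral density on a uniform frequency grid.

    ``power`` has shape ``(n_freqs,)`` or ``(..., n_freqs)``; the units are
    signal²/Hz so that the Riemann sum over frequency recovers signal power.
    """

    frequencies: np.ndarray
    power: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.power < -1e-30):
            raise ValueError("power must be non-negative")


@dataclass
class BandPowerSeries:
    """Per-window integrated band powers.

    ``values`` has shape ``(n_windows, n_bands, n_channels)``; ``times`` is
    the right edge of each window (causal convention).
    """

    times: np.ndarray
    values: np.ndarray
    band_names: list[str]
    channel_names: list[str]
    window_length: float
    step: int


# ---------------------------------------------------------------------------
# preprocessing


def bandpass_fft(signal: SampledSignal, low_cut: float = 0.5,
                 high_cut: float = 40.0) -> SampledSignal:
    """Ideal band-pass via an FFT brick-wall mask.

    Per channel: forward DFT, zero every bin whose |frequency| falls outside
    ``[low_cut, high_cut]``, inverse DFT.  The mask acts symmetrically on
    positive and negative frequencies so the output stays real.  Idempotent.
    """
    nyquist = signal.sampling_rate / 2
    if not (0 <= low_cut < high_cut):
        raise ValueError("need 0 <= low_cut < high_cut")
    if high_cut > nyquist:
        raise ValueError(f"high_cut {high_cut} Hz exceeds Nyquist {nyquist} Hz")
    n = signal.n_samples
    if n == 0:
        return replace(signal, values=signal.values.copy())
    freqs = np.abs(np.fft.fftfreq(n, d=1.0 / signal.sampling_rate))
    mask = (freqs >= low_cut) & (freqs <= high_cut)
    spectrum = np.fft.fft(signal.values, axis=0)
    filtered = np.fft.ifft(spectrum * mask[:, None], axis=0).real
    return replace(signal, values=filtered)


def average_reference(signal: SampledSignal) -> SampledSignal:
    """Subtract the instantaneous cross-channel mean from every channel."""
    if signal.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    mean = signal.values.mean(axis=1, keepdims=True)
    return replace(signal, values=signal.values - mean)


def drop_channels(signal: SampledSignal, names: list[str]) -> SampledSignal:
    """Remove the listed channels, preserving the order of the survivors."""
    unknown = [n for n in names if n not in signal.channel_names]
    if unknown:
        raise KeyError(f"unknown channel(s) {unknown}")
    keep = [i for i, n in enumerate(signal.channel_names) if n not in names]
    return replace(
        signal,
        channel_names=[signal.channel_names[i] for i in keep],
        values=signal.values[:, keep].copy(),
    )


# ---------------------------------------------------------------------------
# spectral estimation


def welch_psd(window_values: np.ndarray, sampling_rate: float,
              segment_length: int | None = None,
              window_fn: str = "hann") -> PsdEstimate:
    """Welch PSD: averaged tapered periodograms over non-overlapping segments.

    ``segment_length`` defaults to the full input length (a single segment).
    Density scaling: ``P = |DFT(w·x)|² / (fs · Σw²)``, doubled on the
    one-sided grid except at DC and Nyquist, so ``Σ P·Δf`` equals signal
    power.  With one segment and a rectangular taper this is exactly the raw
    periodogram.
    """
    arr = np.asarray(window_values, dtype=float)
    was_1d = arr.ndim == 1
    x = np.atleast_2d(arr)
    if x.shape[-1] == 0:
        raise ValueError("empty input")
    n = x.shape[-1]
    nperseg = n if segment_length is None else int(segment_length)
    if not 0 < nperseg <= n:
        raise ValueError("segment_length must be in (0, window length]")
    n_segments = n // nperseg
    segments = x[..., : n_segments * nperseg].reshape(*x.shape[:-1], n_segments, nperseg)
    taper = get_window(window_fn, nperseg, fftbins=True)
    norm_w = float(np.sum(taper**2))
    spec = np.fft.rfft(segments * taper, axis=-1)
    p = (spec.real**2 + spec.imag**2) / (sampling_rate * norm_w)
    p[..., 1:] *= 2.0
    if nperseg % 2 == 0:  # Nyquist bin present and unpaired
        p[..., -1] /= 2.0
    power = p.mean(axis=-2)
    if was_1d:
        power = power[0]
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / sampling_rate)
    df = sampling_rate / nperseg
    return PsdEstimate(frequencies=freqs, power=power, resolution=df)


def band_power(psd: PsdEstimate, bands: list[BandDefinition] | None = None
               ) -> np.ndarray:
    """Riemann-sum band power: ``Σ P(f)·Δf`` over bins with center in [f1, f2).

    Returns shape ``(..., n_bands)`` in units of signal² (power).
    """
    bands = DEFAULT_BANDS if bands is None else bands
    grid_lo = psd.frequencies[0] - psd.resolution / 2
    grid_hi = psd.frequencies[-1] + psd.resolution / 2
    out = np.empty(psd.power.shape[:-1] + (len(bands),))
    for k, band in enumerate(bands):
        if band.f1 < grid_lo or band.f2 > grid_hi:
            raise ValueError(
                f"band {band.name} [{band.f1},{band.f2}) outside the "
                f"frequency grid [{grid_lo},{grid_hi})"
            )
        sel = (psd.frequencies >= band.f1) & (psd.frequencies < band.f2)
        out[..., k] = psd.power[..., sel].sum(axis=-1) * psd.resolution
    return out


def sliding_band_power(signal: SampledSignal, window_length: float = 0.5,
                       step: int = 1,
                       bands: list[BandDefinition] | None = None,
                       segment_length: int | None = None,
                       window_fn: str = "hann") -> BandPowerSeries:
    """Band powers on every sliding-window placement.

    ``n_windows = floor((n_samples − win) / step) + 1``; window ``i`` covers
    samples ``[i·step, i·step + win)`` and is stamped with its right-edge
    time.  A one-sample step reproduces a point-by-point analysis; coarser
    steps trade resolution for speed.
    """
    bands = DEFAULT_BANDS if bands is None else bands
    win = int(round(window_length * signal.sampling_rate))
    if win < 8:
        raise ValueError("window must cover at least 8 samples")
    if win > signal.n_samples:
        raise ValueError("window longer than signal")
    if step < 1:
        raise ValueError("step must be >= 1 sample")
    # (n_windows, n_channels, win): window axis appended last, time decimated
    windows = sliding_window_view(signal.values, win, axis=0)[::step]
    psd = welch_psd(
        windows,
        signal.sampling_rate,
        segment_length=segment_length,
        window_fn=window_fn,
    )
    powers = band_power(psd, bands)  # (n_windows, n_channels, n_bands)
    powers = np.atleast_3d(powers)
    n_windows = windows.shape[0]
    right_edges = (signal.start_time
                   + (np.arange(n_windows) * step + win) / signal.sampling_rate)
    return BandPowerSeries(
        times=right_edges,
        values=np.swapaxes(powers, 1, 2),  # (n_windows, n_bands, n_channels)
        band_names=[b.name for b in bands],
        channel_names=list(signal.channel_names),
        window_length=window_length,
        step=step,
    )
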