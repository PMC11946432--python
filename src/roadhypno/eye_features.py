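"""Eye-movement cleaning, linear-phase FIR filtering, smoothing, and
locally linear embedding.

Pupil diameter, gaze velocity and inter-pupillary distance arrive from a
wearable eye tracker with dropouts (blinks, tracking loss) and slow drift
(ambient light).  The chain is: invalid/outlier repair by interpolation, a
windowed-sinc low-pass to remove measurement jitter, a gentle high-pass to
remove drift, a short moving average, and optionally a locally linear
embedding (LLE) of the joint eye state onto a low-dimensional manifold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import eigh, solve
from scipy.signal import fftconvolve
from sklearn.neighbors import NearestNeighbors

from .timeline_io import SampledSignal

__all__ = [
    "FirFilter",
    "LleEmbedding",
    "clean_eye",
    "design_fir",
    "apply_fir",
    "moving_average",
    "lle_embed",
]

#: physiological pupil-diameter limits, mm
PUPIL_RANGE = (1.5, 9.0)
#: robust outlier threshold, multiples of the per-channel MAD
MAD_THRESHOLD = 5.0


@dataclass(frozen=True)
class FirFilter:
    """Linear-phase windowed-sinc FIR filter.

    Coefficients are symmetric (``h[k] == h[M-1-k]``), giving a constant
    group delay of ``(M-1)/2`` samples.  A low-pass has unit DC gain; a
    high-pass (built by spectral inversion) has zero DC gain.
    """

    coefficients: np.ndarray
    order: int
    cutoff: float
    sampling_rate: float
    mode: str  # "lowpass" | "highpass"

    @property
    def group_delay(self) -> int:
        return (self.order - 1) // 2

    def frequency_response(self, freqs: np.ndarray) -> np.ndarray:
        """Complex response H(f) evaluated by direct summation."""
        k = np.arange(self.order)
        phase = np.exp(-2j * np.pi * np.outer(freqs / self.sampling_rate, k))
        return phase @ self.coefficients


def _sinc_lowpass(fc: float, fs: float, m: int) -> np.ndarray:
    """Raw (untapered) ideal low-pass impulse response of odd length m."""
    k = np.arange(m)
    center = (m - 1) / 2
    h = np.empty(m)
    off = k - center
    nz = off != 0
    h[nz] = np.sin(2 * np.pi * (fc / fs) * off[nz]) / (np.pi * off[nz])
    h[~nz] = 2 * fc / fs
    return h


def design_fir(fc: float, fs: float, m: int, mode: str = "lowpass") -> FirFilter:
    """Windowed-sinc FIR design with a Hamming taper.

    Low-pass: truncated sinc, Hamming-tapered, normalized to unit DC gain.
    High-pass: spectral inversion of the complementary low-pass (negate all
    coefficients, add 1 at the center tap), giving zero DC gain.
    ``m`` must be odd so that the delay ``(m-1)/2`` is an integer.
    """
    if m % 2 == 0:
        raise ValueError("filter order M must be odd")
    if not 0 < fc < fs / 2:
        raise ValueError("cutoff must satisfy 0 < fc < fs/2")
    if mode not in ("lowpass", "highpass"):
        raise ValueError(f"unknown mode {mode!r}")
    taper = np.hamming(m)
    h = _sinc_lowpass(fc, fs, m) * taper
    h = h / h.sum()  # unit DC gain
    if mode == "highpass":
        h = -h
        h[(m - 1) // 2] += 1.0
    return FirFilter(coefficients=h, order=m, cutoff=fc, sampling_rate=fs, mode=mode)


def apply_fir(signal: SampledSignal, fir: FirFilter) -> SampledSignal:
    """Zero-delay FIR filtering with reflection-padded edges.

    Direct-form convolution ``y[n] = Σ h[k] x[n-k]``, with the constant
    ``(M-1)/2``-sample group delay compensated so output sample ``n`` is
    aligned with input sample ``n``.
    """
    m = fir.order
    if signal.n_samples <= m:
        raise ValueError(f"signal ({signal.n_samples} samples) shorter than filter ({m})")
    pad = fir.group_delay
    x = np.pad(signal.values, ((pad, pad), (0, 0)), mode="reflect")
    y = fftconvolve(x, fir.coefficients[:, None], mode="valid", axes=0)
    return replace(signal, values=y)


def moving_average(signal: SampledSignal, n: int = 20) -> SampledSignal:
    """Trailing mean over the last ``n`` samples (prefix mean at the start)."""
    if n < 1:
        raise ValueError("window must be >= 1 sample")
    if n == 1:
        return replace(signal, values=signal.values.copy())
    csum = np.cumsum(signal.values, axis=0)
    out = np.empty_like(signal.values)
    counts = np.minimum(np.arange(1, signal.n_samples + 1), n)
    out[:n] = csum[:n]
    out[n:] = csum[n:] - csum[:-n]
    out /= counts[:, None]
    return replace(signal, values=out)


def clean_eye(signal: SampledSignal,
              pupil_range: tuple[float, float] = PUPIL_RANGE,
              mad_threshold: float = MAD_THRESHOLD) -> SampledSignal:
    """Repair invalid and outlier samples by linear interpolation.

    A sample is invalid if the ``valid`` flag (when present) is 0, if a
    pupil-diameter channel leaves the physiological range, or if any channel
    deviates from its median by more than ``mad_threshold`` scaled MADs.
    Interior invalid runs are linearly interpolated from the nearest valid
    neighbours; leading/trailing runs are held at the nearest valid value.
    """
    values = signal.values.copy()
    names = signal.channel_names
    has_flag = "valid" in names
    flag_ok = signal.channel("valid").astype(bool) if has_flag else np.ones(
        signal.n_samples, dtype=bool)
    t = np.arange(signal.n_samples)
    for i, name in enumerate(names):
        if name == "valid":
            continue
        col = values[:, i]
        ok = flag_ok.copy()
        if name.startswith("pupil_diameter"):
            ok &= (col >= pupil_range[0]) & (col <= pupil_range[1])
        med = np.median(col[ok]) if ok.any() else np.nan
        mad = 1.4826 * np.median(np.abs(col[ok] - med)) if ok.any() else np.nan
        if ok.any() and mad > 0:
            ok &= np.abs(col - med) <= mad_threshold * mad
        if not ok.any():
            raise ValueError(f"channel {name!r}: every sample is invalid")
        values[:, i] = np.interp(t, t[ok], col[ok])
    if has_flag:
        values[:, names.index("valid")] = 1.0
    return replace(signal, values=values)


# ---------------------------------------------------------------------------
# locally linear embedding


@dataclass
class LleEmbedding:
    """LLE result: coordinates, neighbour reconstruction weights, spectrum."""

    coordinates: np.ndarray  # (n_points, d)
    n_neighbors: int
    weights: np.ndarray  # (n_points, n_points), rows sum to 1, K non-zeros
    eigenvalues: np.ndarray  # the d smallest non-trivial eigenvalues


def lle_embed(points: np.ndarray, n_neighbors: int = 12, n_components: int = 2,
              reg: float = 1e-3, symmetrize: bool = False) -> LleEmbedding:
    """Locally linear embedding of ``points`` (shape ``(n, p)``).

    Steps: (i) K nearest neighbours per point by Euclidean distance;
    (ii) reconstruction weights minimizing ``‖x_i − Σ_j w_ij x_j‖²`` subject
    to ``Σ_j w_ij = 1``, with trace-scaled Tikhonov regularization ``reg`` on
    each local Gram matrix; (iii) coordinates are the eigenvectors of
    ``(I−W)ᵀ(I−W)`` for the ``n_components`` smallest eigenvalues above the
    trivial constant mode.

    ``symmetrize`` optionally replaces W by ``(W+Wᵀ)/2`` before the
    eigenproblem; this trades the exact row-sum property of the weights for
    a symmetric affinity and is off by default.
    """
    x = np.asarray(points, dtype=float)
    n, p = x.shape
    k, d = int(n_neighbors), int(n_components)
    if k >= n:
        raise ValueError(f"need n_neighbors < n_points ({k} >= {n})")
    if not 1 <= d < p:
        raise ValueError("need 1 <= n_components < n_features")
    if np.allclose(x, x[0], atol=1e-12):
        raise ValueError("degenerate input: all points identical")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    idx = nn.kneighbors(x, return_distance=False)[:, 1:]  # drop self

    w = np.zeros((n, n))
    ones = np.ones(k)
    for i in range(n):
        z = x[idx[i]] - x[i]  # (k, p) local coordinates
        gram = z @ z.T
        trace = np.trace(gram)
        gram.flat[:: k + 1] += reg * (trace if trace > 0 else 1.0)
        wi = solve(gram, ones, assume_a="pos")
        w[i, idx[i]] = wi / wi.sum()

    w_eff = (w + w.T) / 2 if symmetrize else w
    m = np.eye(n) - w_eff
    m = m.T @ m
    # Deflate the trivial constant mode by shifting it above the spectrum;
    # on (near-)degenerate inputs the constant otherwise mixes into the
    # null-space basis that eigh returns.
    shift = 2.0 * np.abs(m).sum(axis=1).max() + 1.0  # > any eigenvalue of m
    m = m + shift * np.full((n, n), 1.0 / n)
    vals, vecs = eigh(m, subset_by_index=(0, d - 1))
    return LleEmbedding(
        coordinates=vecs * np.sqrt(n),
        n_neighbors=k,
        weights=w,
        eigenvalues=vals,
    )
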