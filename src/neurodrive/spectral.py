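"""Welch power-spectrum estimation and band-power feature construction.

The estimator is the classic segment-averaged modified periodogram: split
x(n) of length N into L segments of M samples (step M·(1−overlap)), apply
a data window ω(n), take the squared-magnitude DFT of each windowed
segment normalised by M·U — with U = (1/M)·Σ ω²(n) the window
normalisation factor — and average the L periodograms.  Values are scaled
as power spectral density (per Hz), one-sided, with interior bins doubled
and DC/Nyquist left single.

For the 1-s, 100-sample analysis windows used throughout, the default
configuration M = nfft = 100, L = 1, Hann window yields 51 bins at 1 Hz
spacing over 0–50 Hz.  Band features are the θ (4–8 Hz, 5 bins),
α (8–13 Hz, 6 bins) and β (13–35 Hz, 23 bins) sub-blocks; band edges are
inclusive, so adjacent bands share their edge bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import get_window
from sklearn.base import BaseEstimator, TransformerMixin

#: Inclusive band edges in Hz; at 1 Hz resolution these give 5/6/23 bins.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 35.0),
}

_WINDOW_ALIASES = {
    "rectangular": "boxcar", "boxcar": "boxcar",
    "hanning": "hann", "hann": "hann",
    "hamming": "hamming",
}

DB_FLOOR = 1e-12  # power floor before 10*log10


def window_weights(window: str, M: int) -> np.ndarray:
    """Return ω(n), n = 0..M−1, for a named window (periodic form)."""
    try:
        name = _WINDOW_ALIASES[window]
    except KeyError:
        raise ValueError(f"unknown window {window!r}") from None
    return get_window(name, M, fftbins=True)


def window_norm_factor(window: str | np.ndarray, M: int) -> float:
    """U = (1/M) Σ ω²(n).  Equals 1 for the rectangular window."""
    if M < 1:
        raise ValueError("M must be >= 1")
    w = window if isinstance(window, np.ndarray) else window_weights(window, M)
    return float(np.sum(w * w) / M)


@dataclass(frozen=True)
class WelchConfig:
    """Segmentation and windowing parameters for the Welch estimator."""

    M: int = 100
    overlap: float = 0.0
    window: str = "hanning"
    nfft: int | None = None
    onesided: bool = True

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.nfft is not None and self.nfft < self.M:
            raise ValueError("nfft must be >= M")

    @property
    def step(self) -> int:
        s = int(round(self.M * (1.0 - self.overlap)))
        return max(s, 1)

    def n_segments(self, N: int) -> int:
        if N < self.M:
            raise ValueError(f"input length {N} shorter than segment length {self.M}")
        return (N - self.M) // self.step + 1

    @property
    def fft_length(self) -> int:
        return self.M if self.nfft is None else self.nfft


@dataclass
class PSDMatrix:
    """Frequency-bin x channel power spectra."""

    values: np.ndarray          # (n_bins, n_channels)
    freqs: np.ndarray           # bin centers, Hz
    in_db: bool = False
    normalized: bool = False
    degenerate_channels: list[int] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class BandFeatures:
    """θ/α/β sub-blocks of a PSD matrix (bins x channels each)."""

    theta: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    label: str | None = None

    @property
    def n_channels(self) -> int:
        return self.theta.shape[1]


# ---------------------------------------------------------------------------
# core estimator
# ---------------------------------------------------------------------------

def segment_data(x: np.ndarray, cfg: WelchConfig) -> np.ndarray:
    """Split the last axis into overlapping segments: (..., L, M)."""
    x = np.asarray(x, dtype=np.float64)
    N = x.shape[-1]
    L = cfg.n_segments(N)
    step = cfg.step
    idx = np.arange(cfg.M)[None, :] + step * np.arange(L)[:, None]
    return x[..., idx]


def welch_psd(data: np.ndarray, fs: float, cfg: WelchConfig | None = None) -> PSDMatrix:
    """Welch PSD of a channels x samples array (or 1-D signal).

    Returns density-scaled power (units²/Hz) on the one-sided frequency
    grid k·fs/nfft.
    """
    cfg = cfg or WelchConfig()
    x = np.atleast_2d(np.asarray(data, dtype=np.float64))   # (C, N)
    segs = segment_data(x, cfg)                              # (C, L, M)
    w = window_weights(cfg.window, cfg.M)
    U = window_norm_factor(w, cfg.M)
    nfft = cfg.fft_length
    spec = np.fft.rfft(segs * w, n=nfft, axis=-1)            # (C, L, nbins)
    pxx = (spec.real ** 2 + spec.imag ** 2) / (cfg.M * U * fs)
    # one-sided: double interior bins (not DC; not Nyquist when nfft even)
    if nfft % 2 == 0:
        pxx[..., 1:-1] *= 2.0
    else:
        pxx[..., 1:] *= 2.0
    values = pxx.mean(axis=1).T                              # (nbins, C)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return PSDMatrix(values=values, freqs=freqs)


def periodogram_oracle(x: np.ndarray, fs: float, cfg: WelchConfig) -> np.ndarray:
    """Deliberately naive reference: per-segment periodograms computed one
    by one with an explicit DFT sum, then averaged.  Used as the
    independent oracle for :func:`welch_psd` in the test suite."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("oracle operates on one channel at a time")
    w = window_weights(cfg.window, cfg.M)
    U = window_norm_factor(w, cfg.M)
    nfft = cfg.fft_length
    L = cfg.n_segments(x.shape[-1])
    step = cfg.step
    n = np.arange(cfg.M)
    k = np.arange(nfft // 2 + 1)
    # explicit e^{-j 2π k n / nfft} matrix
    E = np.exp(-2j * np.pi * np.outer(k, n) / nfft)
    acc = np.zeros(nfft // 2 + 1)
    for i in range(L):
        seg = x[i * step:i * step + cfg.M] * w
        X = E @ seg
        I = (np.abs(X) ** 2) / (cfg.M * U * fs)
        acc += I
    acc /= L
    if nfft % 2 == 0:
        acc[1:-1] *= 2.0
    else:
        acc[1:] *= 2.0
    return acc


# ---------------------------------------------------------------------------
# dB conversion + normalisation, band extraction
# ---------------------------------------------------------------------------

def psd_to_db_norm(psd: PSDMatrix, floor: float = DB_FLOOR) -> PSDMatrix:
    """Convert to dB, then z-score each channel across its frequency bins.

    The normalisation is per channel *within the sample* (stateless, so
    the transform is usable unchanged in the online loop).  A channel
    with zero spread (sd undefined after dB) is flagged and zero-filled.
    """
    if psd.in_db:
        raise ValueError("PSD already in dB")
    db = 10.0 * np.log10(np.maximum(psd.values, floor))
    mean = db.mean(axis=0, keepdims=True)
    sd = db.std(axis=0, keepdims=True)
    degenerate = np.flatnonzero(sd[0] == 0.0)
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    out = (db - mean) / sd_safe
    out[:, degenerate] = 0.0
    return PSDMatrix(values=out, freqs=psd.freqs.copy(), in_db=True,
                     normalized=True, degenerate_channels=list(degenerate))


def band_bin_indices(freqs: np.ndarray, band: str) -> np.ndarray:
    lo, hi = BANDS[band]
    idx = np.flatnonzero((freqs >= lo - 1e-9) & (freqs <= hi + 1e-9))
    if idx.size == 0 or freqs[idx[-1]] < hi - 1e-9:
        raise ValueError(f"band {band} ({lo}-{hi} Hz) exceeds available bins")
    return idx


def extract_bands(psd: PSDMatrix, label: str | None = None) -> BandFeatures:
    """Slice the θ/α/β sub-blocks (inclusive edges, shared edge bins)."""
    blocks = {b: psd.values[band_bin_indices(psd.freqs, b)] for b in BANDS}
    return BandFeatures(theta=blocks["theta"], alpha=blocks["alpha"],
                        beta=blocks["beta"], label=label)


def combined_band_vector(bands: BandFeatures, reducer=np.mean) -> np.ndarray:
    """Reduce each band across bins to one value per channel and
    concatenate θ‖α‖β: 3 x 59 channels -> 177 features by default."""
    parts = [reducer(block, axis=0) for block in (bands.theta, bands.alpha, bands.beta)]
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# batch transformers (sklearn-compatible)
# ---------------------------------------------------------------------------

class WelchPSD(TransformerMixin, BaseEstimator):
    """Transformer: windows (n, channels, T) -> PSDs (n, bins, channels)."""

    def __init__(self, fs: float = 100.0, M: int | None = None,
                 overlap: float = 0.0, window: str = "hanning",
                 nfft: int | None = None):
        self.fs = fs
        self.M = M
        self.overlap = overlap
        self.window = window
        self.nfft = nfft

    def _config(self, T: int) -> WelchConfig:
        M = self.M if self.M is not None else T
        return WelchConfig(M=M, overlap=self.overlap, window=self.window,
                           nfft=self.nfft)

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("expected (n_windows, n_channels, T)")
        cfg = self._config(X.shape[-1])
        out = [welch_psd(x, self.fs, cfg).values for x in X]
        return np.stack(out)

    def freqs(self, T: int) -> np.ndarray:
        cfg = self._config(T)
        return np.fft.rfftfreq(cfg.fft_length, d=1.0 / self.fs)


class PSDNormalizer(TransformerMixin, BaseEstimator):
    """Transformer: dB conversion + per-channel z-scoring across bins,
    applied independently to each sample (n, bins, channels)."""

    def __init__(self, floor: float = DB_FLOOR):
        self.floor = floor

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        db = 10.0 * np.log10(np.maximum(X, self.floor))
        mean = db.mean(axis=1, keepdims=True)
        sd = db.std(axis=1, keepdims=True)
        sd = np.where(sd == 0.0, 1.0, sd)
        return (db - mean) / sd


class BandPowerVectorizer(TransformerMixin, BaseEstimator):
    """Transformer: PSDs (n, bins, channels) -> flat band-power features.

    ``bands="three"`` reduces each of θ/α/β across bins (default: mean)
    and concatenates, giving 3·channels features (177 for 59 channels).
    ``bands="full"`` flattens every bin x channel value (the full-band
    comparison arm).
    """

    def __init__(self, fs: float = 100.0, nfft: int = 100, bands: str = "three",
                 reducer=None):
        self.fs = fs
        self.nfft = nfft
        self.bands = bands
        self.reducer = reducer

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if self.bands == "full":
            return X.reshape(X.shape[0], -1)
        freqs = np.fft.rfftfreq(self.nfft, d=1.0 / self.fs)
        reducer = self.reducer if self.reducer is not None else np.mean
        parts = []
        for b in BANDS:
            idx = band_bin_indices(freqs, b)
            parts.append(reducer(X[:, idx, :], axis=1))
        return np.concatenate(parts, axis=1)
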