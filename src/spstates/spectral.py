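"""Sliding short-term spectral analysis and dominant-peak detection.

The atomic observation of the method is the *spectral pattern* (SP): the
power spectrum of one 2-s Hann-tapered window, restricted to 1-30 Hz at
0.5 Hz resolution (59 bins). Windows slide by 50 samples (0.390625 s at
128 Hz), so a 60-s channel yields 149 SPs. Power is kept on the raw
(non-log) scale because downstream classification correlates SP *shapes*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SpectralConfig",
    "SpectralPattern",
    "BIN_FREQS",
    "N_BINS",
    "bin_frequency",
    "n_windows",
    "sliding_spectra",
    "detect_peaks",
    "SlidingSpectrogram",
]

#: Frequencies of the 59 in-band bins: 1.0, 1.5, ..., 30.0 Hz.
BIN_FREQS = np.arange(1.0, 30.0 + 0.25, 0.5)
N_BINS = BIN_FREQS.size  # 59


@dataclass(frozen=True)
class SpectralConfig:
    """Sliding-window parameters.

    window_len * fs samples per window gives bin spacing 1/window_len;
    the defaults (2 s at 128 Hz, shift 50 samples) give 0.5 Hz bins and
    a 0.390625 s lag between consecutive SPs.
    """

    window_len: float = 2.0
    shift: int = 50
    band: tuple[float, float] = (1.0, 30.0)
    taper: str = "hann"

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_len * fs))


@dataclass
class SpectralPattern:
    """One short-term power spectrum (59 nonnegative values, not logged)."""

    power: np.ndarray
    window_index: int = 0
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {self.power.shape}")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


def bin_frequency(k: int | np.ndarray) -> float | np.ndarray:
    """Centre frequency of bin ``k``: 1.0 + 0.5*k Hz for k = 0..58."""
    return 1.0 + 0.5 * np.asarray(k)


def n_windows(n_samples: int, fs: float = 128.0, cfg: SpectralConfig | None = None) -> int:
    """Number of sliding windows that fit in ``n_samples``.

    floor((N - window) / shift) + 1; window k covers samples
    [shift*k, shift*k + window).
    """
    cfg = cfg or SpectralConfig()
    win = cfg.window_samples(fs)
    if n_samples < win:
        return 0
    return (n_samples - win) // cfg.shift + 1


def sliding_spectra(
    signal: np.ndarray, fs: float = 128.0, cfg: SpectralConfig | None = None
) -> np.ndarray:
    """Compute the sequence of spectral patterns for one channel.

    Parameters
    ----------
    signal : 1-D array of samples at ``fs`` (microvolts).
    fs : sampling rate, Hz.
    cfg : SpectralConfig

    Returns
    -------
    ndarray, shape (n_windows, 59)
        Tapered-periodogram power in the 1-30 Hz bins, window by window.
        Scaling is the plain magnitude-squared of the Hann-tapered DFT
        (any fixed positive scale is equivalent downstream, since the
        classifier correlates shapes).
    """
    cfg = cfg or SpectralConfig()
    signal = np.asarray(signal, dtype=float).ravel()
    win = cfg.window_samples(fs)
    if signal.size < win:
        raise ValueError(
            f"signal of {signal.size} samples is shorter than one "
            f"{win}-sample window"
        )
    nw = n_windows(signal.size, fs, cfg)
    starts = cfg.shift * np.arange(nw)
    idx = starts[:, None] + np.arange(win)[None, :]
    frames = signal[idx] * hann(win, sym=False)
    spec = np.fft.rfft(frames, axis=1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    lo, hi = cfg.band
    keep = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    return power[:, keep]


def detect_peaks(power: np.ndarray, threshold: float = 0.60) -> np.ndarray:
    """Dominant peaks of one SP: strict local maxima above the 60% rule.

    A bin is a peak when it is greater than both neighbours (edge bins:
    greater than their single neighbour) and its value exceeds
    ``threshold`` times the SP maximum. For a plateau of equal adjacent
    values, only the leftmost bin qualifies, and only when the plateau is
    strictly above both plateau-external neighbours. A flat or all-zero
    spectrum has no peaks.

    Returns sorted bin indices (0-based into the 59-bin grid).
    """
    p = np.asarray(power, dtype=float).ravel()
    n = p.size
    if n == 0 or np.all(p == 0):
        return np.array([], dtype=int)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and p[j + 1] == p[i]:
            j += 1
        left_ok = i == 0 or p[i] > p[i - 1]
        right_ok = j == n - 1 or p[j] > p[j + 1]
        # a run spanning the whole array (flat spectrum) is not a peak
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            peaks.append(i)
        i = j + 1
    peaks = np.array(peaks, dtype=int)
    cut = threshold * p.max()
    return peaks[p[peaks] > cut]


class SlidingSpectrogram(TransformerMixin, BaseEstimator):
    """Transformer form of the sliding spectral analysis.

    ``transform`` maps a (channels x samples) array to a list of
    (n_windows x 59) SP matrices, one per channel. Stateless; ``fit`` is
    a no-op kept for pipeline compatibility.
    """

    def __init__(self, fs: float = 128.0, window_len: float = 2.0, shift: int = 50,
                 band: tuple[float, float] = (1.0, 30.0)):
        self.fs = fs
        self.window_len = window_len
        self.shift = shift
        self.band = band

    def _cfg(self) -> SpectralConfig:
        return SpectralConfig(window_len=self.window_len, shift=self.shift,
                              band=self.band)

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> list[np.ndarray]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return [sliding_spectra(ch, self.fs, self._cfg()) for ch in X]
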