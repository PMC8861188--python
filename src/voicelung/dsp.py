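"""Frame-level acoustic descriptors on a fixed frame/hop grid.

All features are defined in closed form on centre-padded frames so that any
value can be recomputed from a direct DFT of the same windowed frame:

- ``rms``        sqrt(mean(x^2)) of the raw frame
- ``mean_amp``   mean(|x|) of the raw frame
- ``zcr``        sign changes / (frame_length - 1)
- ``centroid``   sum(f * S) / sum(S) on the magnitude spectrum
- ``bandwidth``  sqrt(sum(S * (f - centroid)^2) / sum(S))
- ``rolloff(q)`` smallest frequency below which a fraction q of the total
                 spectral magnitude lies (q in {0.85, 0.95})
- ``flatness``   geometric / arithmetic mean of the power spectrum
- ``contrast``   mean over octave sub-bands of the dB gap between the
                 top-alpha and bottom-alpha magnitudes in the band

Degenerate (all-zero) frames follow a documented convention: centroid,
bandwidth and rolloff are 0 and flatness is 1 (the epsilon floor makes the
power spectrum uniform).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

#: amplitude floor used inside logs and the flatness ratio
EPS = 1e-10

#: canonical per-frame feature column order
FRAME_FEATURE_COLUMNS = [
    "rms",
    "mean_amp",
    "zcr",
    "centroid",
    "bandwidth",
    "rolloff85",
    "rolloff95",
    "flatness",
    "contrast",
]


@dataclass(frozen=True)
class FrameGrid:
    """Frame/hop geometry shared by every per-frame computation.

    Parameters
    ----------
    sample_rate : int
        Sampling rate in Hz.
    frame_length : int
        Analysis frame length in samples (default 2048).
    hop_length : int
        Hop between successive frame starts in samples (default 512).
    window : str
        Taper name understood by :func:`scipy.signal.get_window`.
    """

    sample_rate: int = 22050
    frame_length: int = 2048
    hop_length: int = 512
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not (0 < self.hop_length <= self.frame_length):
            raise ValueError("require 0 < hop_length <= frame_length")

    @property
    def n_bins(self) -> int:
        return self.frame_length // 2 + 1

    def frequencies(self) -> np.ndarray:
        """Centre frequency of each rFFT bin, in Hz."""
        return np.fft.rfftfreq(self.frame_length, d=1.0 / self.sample_rate)

    def frame_times(self, n_frames: int) -> np.ndarray:
        """Time of each frame centre under centre-padding: i * hop / sr."""
        return np.arange(n_frames) * self.hop_length / self.sample_rate

    def window_array(self) -> np.ndarray:
        return get_window(self.window, self.frame_length, fftbins=True)


def _frame_signal(waveform: np.ndarray, grid: FrameGrid) -> np.ndarray:
    """Centre-pad with zeros and slice into overlapping frames.

    Returns an array of shape (n_frames, frame_length) where frame i covers
    samples [i*hop - frame_length/2, i*hop + frame_length/2) of the original
    signal, so frame i is centred at time i*hop/sr.
    """
    y = np.asarray(waveform, dtype=np.float64).ravel()
    if y.size == 0:
        raise ValueError("waveform is empty")
    if not np.all(np.isfinite(y)):
        raise ValueError("waveform contains non-finite samples")
    pad = grid.frame_length // 2
    y = np.pad(y, pad, mode="constant")
    frames = sliding_window_view(y, grid.frame_length)[:: grid.hop_length]
    return frames


def stft_magnitude(waveform: np.ndarray, grid: FrameGrid) -> np.ndarray:
    """Magnitude spectrogram, shape (n_frames, frame_length // 2 + 1)."""
    frames = _frame_signal(waveform, grid)
    win = grid.window_array()
    return np.abs(np.fft.rfft(frames * win, axis=1))


def frame_time_features(
    waveform: np.ndarray, grid: FrameGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame (rms, mean_amp, zcr) on the unwindowed centred frames."""
    frames = _frame_signal(waveform, grid)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    mean_amp = np.mean(np.abs(frames), axis=1)
    sign_changes = np.diff(np.signbit(frames), axis=1).sum(axis=1)
    zcr = sign_changes / (grid.frame_length - 1)
    return rms, mean_amp, zcr


def spectral_centroid(spectrogram: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    total = spectrogram.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (spectrogram * freqs).sum(axis=1) / total
    return np.where(total > 0, c, 0.0)


def spectral_bandwidth(
    spectrogram: np.ndarray, freqs: np.ndarray, centroid: np.ndarray
) -> np.ndarray:
    total = spectrogram.sum(axis=1)
    dev = (freqs[None, :] - centroid[:, None]) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        bw = np.sqrt((spectrogram * dev).sum(axis=1) / total)
    return np.where(total > 0, bw, 0.0)


def spectral_rolloff(
    spectrogram: np.ndarray, freqs: np.ndarray, q: float
) -> np.ndarray:
    """Smallest frequency f_K with cumulative magnitude >= q * total."""
    csum = np.cumsum(spectrogram, axis=1)
    total = csum[:, -1]
    # first index where cumulative sum crosses the quantile of the total
    idx = np.argmax(csum >= q * total[:, None], axis=1)
    out = freqs[idx]
    return np.where(total > 0, out, 0.0)


def spectral_flatness(spectrogram: np.ndarray) -> np.ndarray:
    """Geometric over arithmetic mean of the epsilon-floored power spectrum."""
    power = spectrogram**2 + EPS
    gmean = np.exp(np.mean(np.log(power), axis=1))
    amean = np.mean(power, axis=1)
    return gmean / amean


def contrast_band_edges(
    sample_rate: int, fmin: float = 200.0, n_bands: int = 6
) -> np.ndarray:
    """Octave-spaced sub-band edges above ``fmin``, capped at Nyquist."""
    edges = fmin * 2.0 ** np.arange(n_bands + 1)
    return np.minimum(edges, sample_rate / 2.0)


def spectral_contrast(
    spectrogram: np.ndarray,
    freqs: np.ndarray,
    sample_rate: int,
    alpha: float = 0.02,
    fmin: float = 200.0,
    n_bands: int = 6,
) -> np.ndarray:
    """Mean over octave sub-bands of the peak-minus-valley gap in dB.

    Within each band the peak is the mean of the top ``alpha`` fraction of
    magnitudes (at least one bin) and the valley the mean of the bottom
    ``alpha`` fraction; the band contrast is 20*log10(peak/valley) on the
    epsilon-floored values.
    """
    edges = contrast_band_edges(sample_rate, fmin=fmin, n_bands=n_bands)
    band_contrasts = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (freqs >= lo) & (freqs < hi)
        if hi >= sample_rate / 2.0:  # close the top band at Nyquist
            mask = (freqs >= lo) & (freqs <= hi)
        n = int(mask.sum())
        if n == 0:
            continue
        sub = np.sort(spectrogram[:, mask], axis=1)
        k = max(1, int(alpha * n))
        valley = sub[:, :k].mean(axis=1)
        peak = sub[:, -k:].mean(axis=1)
        band_contrasts.append(
            20.0 * (np.log10(peak + EPS) - np.log10(valley + EPS))
        )
    if not band_contrasts:
        return np.zeros(spectrogram.shape[0])
    return np.mean(band_contrasts, axis=0)


def frame_spectral_features(
    spectrogram: np.ndarray, grid: FrameGrid
) -> dict[str, np.ndarray]:
    """All spectral descriptors for a magnitude spectrogram.

    Centroid, bandwidth and rolloff use magnitude spectra; flatness uses the
    power spectrum — the conventional definitions.
    """
    S = np.asarray(spectrogram, dtype=np.float64)
    if np.any(S < 0):
        raise ValueError("spectrogram must be non-negative")
    freqs = grid.frequencies()
    centroid = spectral_centroid(S, freqs)
    return {
        "centroid": centroid,
        "bandwidth": spectral_bandwidth(S, freqs, centroid),
        "rolloff85": spectral_rolloff(S, freqs, 0.85),
        "rolloff95": spectral_rolloff(S, freqs, 0.95),
        "flatness": spectral_flatness(S),
        "contrast": spectral_contrast(S, freqs, grid.sample_rate),
    }


def compute_frame_features(waveform: np.ndarray, grid: FrameGrid) -> pd.DataFrame:
    """Full per-frame feature matrix for one recording.

    Returns a DataFrame with a ``time_s`` column (frame centres) followed by
    the canonical columns in :data:`FRAME_FEATURE_COLUMNS`.
    """
    rms, mean_amp, zcr = frame_time_features(waveform, grid)
    S = stft_magnitude(waveform, grid)
    spec = frame_spectral_features(S, grid)
    out = pd.DataFrame(
        {
            "time_s": grid.frame_times(len(rms)),
            "rms": rms,
            "mean_amp": mean_amp,
            "zcr": zcr,
            **spec,
        }
    )
    return out[["time_s"] + FRAME_FEATURE_COLUMNS]
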