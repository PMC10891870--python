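"""MFCC feature extraction: 13 static cepstra + delta + delta-delta (39-d),
and context splicing for the neural acoustic model.

Pipeline per frame: pre-emphasis (coefficient 0.98), 20 ms frames with a
10 ms hop (full frames only, no padding), Hamming window, power spectrum,
26 triangular mel filters (HTK scale) from 0 Hz to Nyquist, log with floor,
orthonormal DCT-II, coefficients 0..12 kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft
from scipy.signal import get_window
from sklearn.base import BaseEstimator, TransformerMixin

from .audio import AudioSignal

__all__ = [
    "FeatureMatrix",
    "mel_filterbank",
    "frame_signal",
    "compute_mfcc",
    "add_deltas",
    "splice",
    "MFCCExtractor",
]

PRE_EMPHASIS = 0.98
FRAME_LEN_S = 0.020
HOP_S = 0.010
LOG_FLOOR = 1e-10


@dataclass
class FeatureMatrix:
    """T x D feature matrix with its framing metadata (D = 13 or 39)."""

    values: np.ndarray
    sample_rate: int
    frame_len_s: float = FRAME_LEN_S
    hop_s: float = HOP_S

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("feature matrix must be 2-D with T >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, float) / 2595.0) - 1.0)


def mel_filterbank(
    n_filters: int, n_fft: int, sample_rate: int,
    f_min: float = 0.0, f_max: float | None = None,
) -> np.ndarray:
    """Triangular mel filterbank, shape (n_filters, n_fft//2 + 1)."""
    if f_max is None:
        f_max = sample_rate / 2.0
    mel_pts = np.linspace(hz_to_mel(f_min), hz_to_mel(f_max), n_filters + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / sample_rate).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for m in range(1, n_filters + 1):
        lo, ctr, hi = bins[m - 1], bins[m], bins[m + 1]
        for k in range(lo, ctr):
            if ctr > lo:
                fb[m - 1, k] = (k - lo) / (ctr - lo)
        for k in range(ctr, hi):
            if hi > ctr:
                fb[m - 1, k] = (hi - k) / (hi - ctr)
    return fb


def frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Slice into full frames only: T = floor((n - frame_len)/hop) + 1."""
    if x.size < frame_len:
        raise ValueError(
            f"signal of {x.size} samples shorter than one frame ({frame_len})"
        )
    n_frames = (x.size - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def compute_mfcc(
    signal: AudioSignal,
    n_filters: int = 26,
    n_ceps: int = 13,
    pre_emphasis: float = PRE_EMPHASIS,
    frame_len_s: float = FRAME_LEN_S,
    hop_s: float = HOP_S,
) -> FeatureMatrix:
    """Static MFCCs (coefficients 0..n_ceps-1) of a waveform."""
    sr = signal.sample_rate
    x = signal.samples
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - pre_emphasis * x[:-1]
    flen = int(round(frame_len_s * sr))
    hop = int(round(hop_s * sr))
    frames = frame_signal(y, flen, hop)
    window = get_window("hamming", flen, fftbins=True)
    spec = rfft(frames * window, n=flen, axis=1)
    power = np.abs(spec) ** 2
    fb = mel_filterbank(n_filters, flen, sr)
    energies = power @ fb.T
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    ceps = dct(log_e, type=2, norm="ortho", axis=1)[:, :n_ceps]
    return FeatureMatrix(ceps, sr, frame_len_s, hop_s)


def _delta(values: np.ndarray, window: int = 2) -> np.ndarray:
    """Regression delta: d_t = sum_n n (c_{t+n} - c_{t-n}) / (2 sum n^2),
    with edge frames replicated."""
    denom = 2.0 * sum(n * n for n in range(1, window + 1))
    padded = np.pad(values, ((window, window), (0, 0)), mode="edge")
    out = np.zeros_like(values)
    for n in range(1, window + 1):
        out += n * (padded[window + n : padded.shape[0] - window + n]
                    - padded[window - n : padded.shape[0] - window - n])
    return out / denom


def add_deltas(static: FeatureMatrix, window: int = 2) -> FeatureMatrix:
    """Append delta and delta-delta blocks: columns [static | d | dd]."""
    d = _delta(static.values, window)
    dd = _delta(d, window)
    return FeatureMatrix(
        np.hstack([static.values, d, dd]),
        static.sample_rate, static.frame_len_s, static.hop_s,
    )


def splice(features: FeatureMatrix | np.ndarray, context: int = 3) -> np.ndarray:
    """Concatenate each frame with its ``context`` neighbours on each side
    (edge replication): output width D * (2*context + 1), 273 for 39-d
    features with context 3."""
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    padded = np.pad(values, ((context, context), (0, 0)), mode="edge")
    T = values.shape[0]
    blocks = [padded[i : i + T] for i in range(2 * context + 1)]
    return np.hstack(blocks)


class MFCCExtractor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: list of AudioSignal -> list of T x 39 arrays.

    Parameters mirror :func:`compute_mfcc`; ``with_deltas=False`` yields the
    13-d static features instead.
    """

    def __init__(self, n_filters: int = 26, n_ceps: int = 13,
                 pre_emphasis: float = PRE_EMPHASIS,
                 frame_len_s: float = FRAME_LEN_S, hop_s: float = HOP_S,
                 with_deltas: bool = True):
        self.n_filters = n_filters
        self.n_ceps = n_ceps
        self.pre_emphasis = pre_emphasis
        self.frame_len_s = frame_len_s
        self.hop_s = hop_s
        self.with_deltas = with_deltas

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: list[AudioSignal]) -> list[np.ndarray]:
        out = []
        for sig in X:
            fm = compute_mfcc(sig, self.n_filters, self.n_ceps,
                              self.pre_emphasis, self.frame_len_s, self.hop_s)
            if self.with_deltas:
                fm = add_deltas(fm)
            out.append(fm.values)
        return out
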