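"""EMD-TEO cepstral-distance endpoint detection.

Vocalization segments are located in a denoised recording in four stages:

1. empirical mode decomposition (EMD) of the waveform into intrinsic mode
   functions (IMFs);
2. Teager energy operator (TEO) applied to the selected IMFs to obtain a
   frame-level energy track sensitive to both amplitude and frequency;
3. a short-time cepstral-distance track against a noise-reference cepstrum;
4. a two-level decision: a double threshold on the TEO energy seeds and
   extends candidate segments, and the cepstral distance refines frames
   near the candidate boundaries.

Thresholds are adaptive (noise-floor mean + k * std from the leading
noise-only portion), making detection covariant under amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, rfft
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .audio import AudioSignal
from .features import frame_signal

__all__ = [
    "IMFDecomposition",
    "Segment",
    "EndpointConfig",
    "emd",
    "teager_energy",
    "short_time_cepstral_distance",
    "detect_endpoints",
    "EndpointDetector",
]


@dataclass
class IMFDecomposition:
    imfs: list[np.ndarray]
    residual: np.ndarray

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


@dataclass(frozen=True)
class Segment:
    """Half-open 0-based sample interval [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid segment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class EndpointConfig:
    frame_len_s: float = 0.020
    hop_s: float = 0.010
    # adaptive thresholds: noise mean + alpha/beta * noise std
    teo_alpha_high: float = 5.0
    teo_beta_low: float = 2.0
    teo_std_floor_frac: float = 0.2  # deviation scale >= this fraction of mean
    cd_gamma: float = 3.0
    cd_threshold: float | None = None  # absolute override of the adaptive rule
    min_speech_s: float = 0.10
    min_gap_s: float = 0.15
    noise_floor_s: float = 0.10  # leading portion assumed noise-only
    imf_selection: str = "band"  # "band" or "topk"
    imf_band_hz: tuple[float, float] = (100.0, 14000.0)
    imf_top_k: int = 3
    teo_per_imf: bool = False  # TEO per IMF then sum, instead of TEO of sum
    boundary_refine_frames: int = 5
    cd_n_bins: int = 12
    max_imfs: int = 6


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima (strict sign change of the slope)."""
    d = np.diff(x)
    # collapse flat runs so plateaus count once
    s = np.sign(d)
    nz = s != 0
    idx = np.where(nz)[0]
    if idx.size < 2:
        return np.array([], int), np.array([], int)
    changes = np.where(s[idx[:-1]] != s[idx[1:]])[0]
    pts = idx[changes] + 1
    maxima = pts[s[idx[changes]] > 0]
    minima = pts[s[idx[changes]] < 0]
    return maxima, minima


def _sift_once(x: np.ndarray) -> tuple[np.ndarray, int]:
    maxima, minima = _extrema(x)
    n_ext = maxima.size + minima.size
    if maxima.size < 2 or minima.size < 2:
        return x, n_ext
    t = np.arange(x.size)
    # mirror the boundary extrema so the spline does not diverge at the edges
    mx_i = np.concatenate(([2 * maxima[0] - maxima[1]], maxima,
                           [2 * maxima[-1] - maxima[-2]]))
    mx_v = np.concatenate(([x[maxima[1]]], x[maxima], [x[maxima[-2]]]))
    mn_i = np.concatenate(([2 * minima[0] - minima[1]], minima,
                           [2 * minima[-1] - minima[-2]]))
    mn_v = np.concatenate(([x[minima[1]]], x[minima], [x[minima[-2]]]))
    upper = CubicSpline(mx_i, mx_v)(t)
    lower = CubicSpline(mn_i, mn_v)(t)
    return x - 0.5 * (upper + lower), n_ext


def emd(
    signal: AudioSignal | np.ndarray,
    max_imfs: int = 6,
    sift_tolerance: float = 0.2,
    max_sifts: int = 30,
) -> IMFDecomposition:
    """Empirical mode decomposition by envelope sifting.

    Sifting of each IMF stops when the normalized squared change between
    iterations (Huang's SD criterion) drops below ``sift_tolerance`` or after
    ``max_sifts`` iterations; decomposition stops when the residual has too
    few extrema to interpolate or ``max_imfs`` is reached.  The IMFs and
    residual sum back to the input exactly (telescoping construction).
    """
    x = signal.samples if isinstance(signal, AudioSignal) else np.asarray(signal, float)
    if x.size < 8:
        raise ValueError("signal too short for EMD (need >= 8 samples)")
    residual = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        maxima, minima = _extrema(residual)
        if maxima.size + minima.size < 2:
            break
        h = residual.copy()
        for _ in range(max_sifts):
            h_new, n_ext = _sift_once(h)
            if n_ext < 4:
                h = h_new
                break
            denom = float(h @ h)
            sd = float((h - h_new) @ (h - h_new)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sift_tolerance:
                # IMF acceptance: extrema and zero-crossing counts within 1
                mx, mn = _extrema(h)
                zc = int(np.sum(np.abs(np.diff(np.sign(h))) > 0))
                if abs((mx.size + mn.size) - zc) <= 1:
                    break
        imfs.append(h)
        residual = residual - h
    return IMFDecomposition(imfs=imfs, residual=residual)


def teager_energy(x: np.ndarray) -> np.ndarray:
    """Teager energy psi[n] = x(n)^2 - x(n-1) x(n+1); endpoints copied from
    the nearest interior value.  Same length as the input."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError("Teager energy needs at least 3 samples")
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


def _real_cepstrum(frames: np.ndarray, n_bins: int, floor: float = 1e-10) -> np.ndarray:
    spec = np.abs(rfft(frames * np.hamming(frames.shape[1]), axis=1))
    logmag = np.log(np.maximum(spec, floor))
    ceps = irfft(logmag, n=frames.shape[1], axis=1)
    return ceps[:, 1 : n_bins + 1]  # quefrency bins 1..n_bins (c0 excluded)


def short_time_cepstral_distance(
    signal: AudioSignal | np.ndarray,
    sample_rate: int | None = None,
    frame_len_s: float = 0.020,
    hop_s: float = 0.010,
    n_noise_frames: int = 10,
    n_bins: int = 12,
) -> np.ndarray:
    """Per-frame Euclidean distance between each frame's magnitude real
    cepstrum (quefrency bins 1..n_bins) and the mean cepstrum of the first
    ``n_noise_frames`` frames (assumed noise-only)."""
    if isinstance(signal, AudioSignal):
        x, sr = signal.samples, signal.sample_rate
    else:
        if sample_rate is None:
            raise ValueError("sample_rate required for raw arrays")
        x, sr = np.asarray(signal, float), sample_rate
    flen = int(round(frame_len_s * sr))
    hop = int(round(hop_s * sr))
    frames = frame_signal(x, flen, hop)
    ceps = _real_cepstrum(frames, n_bins)
    k = min(n_noise_frames, ceps.shape[0])
    reference = ceps[:k].mean(axis=0)
    return np.sqrt(np.sum((ceps - reference) ** 2, axis=1))


def _double_threshold(track: np.ndarray, high: float, low: float) -> list[tuple[int, int]]:
    """Seed segments where track > high; extend each outward while > low."""
    above_high = track > high
    above_low = track > low
    segments: list[tuple[int, int]] = []
    i = 0
    n = track.size
    while i < n:
        if above_high[i]:
            lo = i
            while lo > 0 and above_low[lo - 1]:
                lo -= 1
            hi = i
            while hi + 1 < n and above_low[hi + 1]:
                hi += 1
            if segments and lo <= segments[-1][1]:
                segments[-1] = (segments[-1][0], hi + 1)
            else:
                segments.append((lo, hi + 1))
            i = hi + 1
        i += 1
    return segments


def select_imfs(decomp: IMFDecomposition, signal: np.ndarray, sample_rate: int,
                config: EndpointConfig) -> list[np.ndarray]:
    """IMF selection: spectral-centroid band rule or top-k by correlation."""
    if not decomp.imfs:
        return [signal]
    if config.imf_selection == "topk":
        corrs = []
        for imf in decomp.imfs:
            denom = np.linalg.norm(imf) * np.linalg.norm(signal)
            corrs.append(abs(imf @ signal) / denom if denom > 0 else 0.0)
        order = np.argsort(corrs)[::-1][: config.imf_top_k]
        return [decomp.imfs[i] for i in sorted(order)]
    lo, hi = config.imf_band_hz
    hi = min(hi, 0.999 * sample_rate / 2.0)
    freqs = np.fft.rfftfreq(signal.size, d=1.0 / sample_rate)
    kept = []
    for imf in decomp.imfs:
        power = np.abs(np.fft.rfft(imf)) ** 2
        total = power.sum()
        centroid = float((freqs * power).sum() / total) if total > 0 else 0.0
        if lo <= centroid <= hi:
            kept.append(imf)
    return kept if kept else list(decomp.imfs)


def detect_endpoints(
    signal: AudioSignal, config: EndpointConfig | None = None
) -> list[Segment]:
    """Two-level endpoint detection; returns sorted non-overlapping segments.

    Silence-only input (nothing above the adaptive thresholds) returns [].
    """
    if config is None:
        config = EndpointConfig()
    sr = signal.sample_rate
    x = signal.samples
    flen = int(round(config.frame_len_s * sr))
    hop = int(round(config.hop_s * sr))
    if x.size < max(flen, 8):
        return []

    decomp = emd(x, max_imfs=config.max_imfs)
    selected = select_imfs(decomp, x, sr, config)
    if config.teo_per_imf:
        teo = np.sum([teager_energy(imf) for imf in selected], axis=0)
    else:
        teo = teager_energy(np.sum(selected, axis=0))
    frame_teo = frame_signal(teo, flen, hop).mean(axis=1)

    n_noise = max(int(round(config.noise_floor_s * sr)) // hop, 1)
    n_noise = min(n_noise, frame_teo.size)
    noise_mean = float(frame_teo[:n_noise].mean())
    # a short noise window underestimates the spread of the frame energies;
    # floor the deviation scale at a fraction of the mean (keeps thresholds
    # covariant under amplitude scaling)
    noise_std = max(float(frame_teo[:n_noise].std()),
                    config.teo_std_floor_frac * noise_mean) + 1e-30
    high = noise_mean + config.teo_alpha_high * noise_std
    low = noise_mean + config.teo_beta_low * noise_std

    frame_segs = _double_threshold(frame_teo, high, low)
    if not frame_segs:
        return []

    # secondary refinement via cepstral distance near candidate boundaries
    cd = short_time_cepstral_distance(
        x, sr, config.frame_len_s, config.hop_s,
        n_noise_frames=n_noise, n_bins=config.cd_n_bins,
    )
    if config.cd_threshold is not None:
        cd_thr = config.cd_threshold
    else:
        cd_thr = float(cd[:n_noise].mean() + config.cd_gamma * cd[:n_noise].std())
    w = config.boundary_refine_frames
    refined = []
    for lo_f, hi_f in frame_segs:
        # contiguous extension only, capped at w frames per boundary
        steps = 0
        while lo_f > 0 and steps < w and cd[lo_f - 1] > cd_thr:
            lo_f -= 1
            steps += 1
        steps = 0
        while hi_f < cd.size and steps < w and cd[hi_f] > cd_thr:
            hi_f += 1
            steps += 1
        refined.append((lo_f, hi_f))

    # merge short gaps, drop short segments, convert frames -> samples
    min_gap_f = max(int(round(config.min_gap_s / config.hop_s)), 1)
    merged: list[tuple[int, int]] = []
    for seg in refined:
        if merged and seg[0] - merged[-1][1] < min_gap_f:
            merged[-1] = (merged[-1][0], max(seg[1], merged[-1][1]))
        else:
            merged.append(seg)
    min_speech = config.min_speech_s * sr
    out = []
    for lo_f, hi_f in merged:
        start = lo_f * hop
        end = min((hi_f - 1) * hop + flen, x.size)
        if end - start >= min_speech:
            out.append(Segment(start, end))
    return out


class EndpointDetector(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: list of AudioSignal -> list of Segment lists."""

    def __init__(self, config: EndpointConfig | None = None):
        self.config = config

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: list[AudioSignal]) -> list[list[Segment]]:
        cfg = self.config or EndpointConfig()
        return [detect_endpoints(sig, cfg) for sig in X]
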