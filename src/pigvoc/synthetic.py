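"""Seeded synthetic vocalization generator with known ground truth.

Each of the five default class specs emulates one vocalization type as a
harmonic source (fundamental f0 with a flat, rising, falling or pulsed
trajectory, plus harmonics at k*f0 with 1/k amplitudes) shaped by a parallel
bank of resonant (formant) filters and an amplitude envelope, embedded in
optional leading/trailing silence, with additive background noise (white
plus a low-passed component below 3 kHz) mixed to a requested SNR.

The five defaults differ in f0 range, trajectory, harmonic count and
formant placement so that their spectra occupy distinct bands; the eating
and panting specs are deliberately confusable (both burst-trains with
overlapping formants) so the classification task is separable but not
trivial.  Everything is deterministic given a seed, and every clip carries
its clean reference and true segment boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import butter, iirpeak, lfilter, sosfilt

from .audio import AudioSignal, DatasetManifest, ManifestEntry, stratified_split, write_wav
from .denoise import snr_db as _snr_db
from .endpointing import Segment

__all__ = [
    "ClassSpec",
    "SyntheticClip",
    "default_class_specs",
    "generate_vocalization",
    "generate_dataset",
    "write_dataset",
]

DEFAULT_SAMPLE_RATE = 16_000
DEFAULT_SNR_DB = 10.0


@dataclass(frozen=True)
class ClassSpec:
    name: str
    f0_range: tuple[float, float]
    f0_trajectory: str = "flat"  # flat | rising | falling | pulsed
    n_harmonics: int = 10
    formant_centers: tuple[float, ...] = ()
    duration_range: tuple[float, float] = (0.3, 0.7)
    amplitude_envelope: str = "sustained"  # sustained | burst-train
    burst_rate_hz: float = 10.0

    def validate(self, sample_rate: int) -> None:
        nyquist = sample_rate / 2.0
        if self.f0_range[1] >= nyquist:
            raise ValueError(f"{self.name}: f0 above Nyquist")
        if self.duration_range[0] <= 0:
            raise ValueError(f"{self.name}: non-positive duration")


@dataclass
class SyntheticClip:
    audio: AudioSignal
    label: str
    true_segments: list[Segment]
    clean_reference: AudioSignal
    snr_db: float


def default_class_specs() -> list[ClassSpec]:
    """Five vocalization classes with distinct spectral bands.

    Harmonic counts and formants are chosen so the occupied bands roughly
    span 0-6 kHz (eating), 0-9 kHz (estrus), 0-14 kHz (howling, clipped to
    Nyquist at low sample rates), 0-4 kHz (humming) and 0-6 kHz (panting);
    eating and panting share their formant region on purpose.
    """
    return [
        ClassSpec("eating", (100.0, 160.0), "pulsed", 24, (800.0, 2500.0),
                  (0.35, 0.7), "burst-train", burst_rate_hz=9.0),
        ClassSpec("estrus", (220.0, 300.0), "rising", 28, (1200.0, 3800.0),
                  (0.4, 0.8), "sustained"),
        ClassSpec("howling", (350.0, 480.0), "falling", 30, (1800.0, 5200.0),
                  (0.45, 0.8), "sustained"),
        ClassSpec("humming", (90.0, 130.0), "flat", 8, (350.0,),
                  (0.4, 0.8), "sustained"),
        ClassSpec("panting", (140.0, 200.0), "pulsed", 22, (900.0, 2600.0),
                  (0.35, 0.7), "burst-train", burst_rate_hz=14.0),
    ]


def _f0_track(spec: ClassSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.f0_range
    base = rng.uniform(lo, hi)
    t = np.linspace(0.0, 1.0, n)
    if spec.f0_trajectory == "flat":
        return np.full(n, base)
    if spec.f0_trajectory == "rising":
        return base + (hi - base) * t
    if spec.f0_trajectory == "falling":
        return base + (lo - base) * t
    if spec.f0_trajectory == "pulsed":
        jitter = 1.0 + 0.06 * np.sin(2.0 * np.pi * spec.burst_rate_hz * t
                                     * n / max(n, 1))
        return np.full(n, base) * jitter
    raise ValueError(f"unknown f0 trajectory {spec.f0_trajectory!r}")


def _envelope(spec: ClassSpec, n: int, sample_rate: int) -> np.ndarray:
    t = np.arange(n) / sample_rate
    edge = max(int(0.02 * sample_rate), 2)
    ramp = np.ones(n)
    e = min(edge, n // 2)
    ramp[:e] = 0.5 * (1.0 - np.cos(np.pi * np.arange(e) / e))
    ramp[n - e:] = ramp[:e][::-1]
    if spec.amplitude_envelope == "sustained":
        return ramp
    if spec.amplitude_envelope == "burst-train":
        pulses = 0.5 * (1.0 - np.cos(2.0 * np.pi * spec.burst_rate_hz * t)) ** 2
        return ramp * (0.15 + 0.85 * pulses)
    raise ValueError(f"unknown envelope {spec.amplitude_envelope!r}")


def _formant_shape(x: np.ndarray, centers: tuple[float, ...],
                   sample_rate: int) -> np.ndarray:
    if not centers:
        return x
    nyquist = sample_rate / 2.0
    out = 0.25 * x  # direct path keeps the fundamental audible
    for f in centers:
        f = min(f, 0.95 * nyquist)
        b, a = iirpeak(f / nyquist, Q=4.0)
        out = out + lfilter(b, a, x)
    peak = np.max(np.abs(out))
    return out / peak if peak > 0 else out


def _background_noise(n: int, sample_rate: int, rng: np.random.Generator) -> np.ndarray:
    """White noise plus a low-passed (< 3 kHz) component, unit-power-ish."""
    white = rng.standard_normal(n)
    cutoff = min(3000.0, 0.45 * sample_rate)
    sos = butter(4, cutoff / (sample_rate / 2.0), output="sos")
    low = sosfilt(sos, rng.standard_normal(n))
    noise = 0.5 * white + 0.5 * low / (np.std(low) + 1e-30)
    return noise / (np.std(noise) + 1e-30)


def generate_vocalization(
    spec: ClassSpec,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    snr_db: float = DEFAULT_SNR_DB,
    silence_range: tuple[float, float] = (0.2, 0.5),
    peak: float = 0.5,
) -> SyntheticClip:
    """One voiced burst embedded in silence plus background noise.

    The noise is scaled so that 10*log10(P_clean / P_noise), summed over the
    whole clip, equals ``snr_db`` exactly.  Deterministic given
    (spec, sample_rate, seed).
    """
    spec.validate(sample_rate)
    rng = np.random.default_rng(seed)
    dur = rng.uniform(*spec.duration_range)
    n_voiced = max(int(round(dur * sample_rate)), 8)
    f0 = _f0_track(spec, n_voiced, rng)
    phase = 2.0 * np.pi * np.cumsum(f0) / sample_rate
    nyquist = sample_rate / 2.0
    voiced = np.zeros(n_voiced)
    for k in range(1, spec.n_harmonics + 1):
        if np.max(f0) * k >= 0.98 * nyquist:
            break
        voiced += np.cos(k * phase + rng.uniform(0, 2 * np.pi)) / k
    voiced = _formant_shape(voiced, spec.formant_centers, sample_rate)
    voiced *= _envelope(spec, n_voiced, sample_rate)
    mx = np.max(np.abs(voiced))
    if mx > 0:
        voiced *= peak / mx

    lead = int(round(rng.uniform(*silence_range) * sample_rate))
    tail = int(round(rng.uniform(*silence_range) * sample_rate))
    clean = np.concatenate([np.zeros(lead), voiced, np.zeros(tail)])
    n = clean.size

    noise = _background_noise(n, sample_rate, rng)
    p_clean = float(np.sum(clean**2))
    p_noise = float(np.sum(noise**2))
    scale = np.sqrt(p_clean / (p_noise * 10.0 ** (snr_db / 10.0)))
    noisy = clean + scale * noise
    mx = np.max(np.abs(noisy))
    if mx > 1.0:  # keep within WAV full scale without changing the SNR
        noisy, clean = noisy / mx, clean / mx

    return SyntheticClip(
        audio=AudioSignal(noisy, sample_rate),
        label=spec.name,
        true_segments=[Segment(lead, lead + n_voiced)],
        clean_reference=AudioSignal(clean, sample_rate),
        snr_db=snr_db,
    )


def generate_dataset(
    specs: list[ClassSpec] | None = None,
    n_per_class: int = 50,
    snr_db: float = DEFAULT_SNR_DB,
    seed: int = 0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    silence_range: tuple[float, float] = (0.0, 0.0),
    train_fraction: float = 0.8,
) -> tuple[list[SyntheticClip], DatasetManifest]:
    """A full labeled dataset of clips with a stratified 8:2 train/test split.

    Clips are pre-segmented by default (no silence padding); pass a nonzero
    ``silence_range`` to embed each vocalization in silence for endpoint-
    detection experiments.  The manifest's ``path`` column holds synthetic
    ids (``<label>_<index>``); :func:`write_dataset` materializes WAV files.
    """
    if specs is None:
        specs = default_class_specs()
    if n_per_class < 4:
        raise ValueError("n_per_class must be >= 4")
    rng = np.random.default_rng(seed)
    clips: list[SyntheticClip] = []
    entries: list[ManifestEntry] = []
    for spec in specs:
        for i in range(n_per_class):
            clip_seed = int(rng.integers(2**31 - 1))
            clip = generate_vocalization(
                spec, sample_rate, clip_seed, snr_db, silence_range=silence_range
            )
            clips.append(clip)
            entries.append(ManifestEntry(f"{spec.name}_{i:04d}.wav", spec.name))
    manifest = DatasetManifest(entries, [s.name for s in specs])
    manifest = stratified_split(manifest, train_fraction, seed=seed)
    return clips, manifest


def write_dataset(clips: list[SyntheticClip], manifest: DatasetManifest,
                  out_dir: str | Path) -> None:
    """Write WAVs, the manifest CSV and a true-boundaries CSV sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["path,start_sample,end_sample"]
    for clip, entry in zip(clips, manifest.entries):
        write_wav(out_dir / entry.path, clip.audio)
        for seg in clip.true_segments:
            lines.append(f"{entry.path},{seg.start},{seg.end}")
    from .audio import save_manifest

    save_manifest(manifest, out_dir / "manifest.csv")
    (out_dir / "boundaries.csv").write_text("\n".join(lines) + "\n")


def measured_snr_db(clip: SyntheticClip) -> float:
    """SNR of a generated clip re-measured against its clean reference."""
    return _snr_db(clip.clean_reference, clip.audio)
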