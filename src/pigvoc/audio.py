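"""WAV input/output, dataset manifests and run configuration.

Everything downstream operates on :class:`AudioSignal`: a mono,
double-precision waveform in [-1, 1] with an explicit sample rate.
PCM conversion happens only at file boundaries.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioSignal",
    "ManifestEntry",
    "DatasetManifest",
    "read_wav",
    "write_wav",
    "resample",
    "stratified_split",
    "load_manifest",
    "save_manifest",
    "load_config",
]

#: Full-scale value of 16-bit PCM; integer samples are divided by this on read.
PCM16_FULL_SCALE = 32768.0

DEFAULT_SAMPLE_RATE = 44_100


class AudioFormatError(ValueError):
    """Raised for unreadable, empty or non-PCM audio files."""


@dataclass(frozen=True)
class AudioSignal:
    """Mono waveform with sample rate.

    Parameters
    ----------
    samples : ndarray of float64, shape (n,)
        Waveform in [-1, 1] (soft convention; enforced on write).
    sample_rate : int
        Sampling rate in Hz, positive.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioSignal must be mono (1-D samples)")
        if samples.size < 1:
            raise ValueError("AudioSignal must contain at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioSignal samples must be finite")
        if not (isinstance(self.sample_rate, (int, np.integer)) and self.sample_rate > 0):
            raise ValueError("sample_rate must be a positive integer")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    label: str
    split: str = "unassigned"


@dataclass
class DatasetManifest:
    """Ordered list of (path, label, split) rows plus the class-label order."""

    entries: list[ManifestEntry]
    class_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.class_labels:
            seen: list[str] = []
            for e in self.entries:
                if e.label not in seen:
                    seen.append(e.label)
            self.class_labels = seen
        labels = set(self.class_labels)
        for e in self.entries:
            if e.label not in labels:
                raise ValueError(f"entry label {e.label!r} not in class_labels")
            if e.split not in ("train", "test", "unassigned"):
                raise ValueError(f"invalid split tag {e.split!r}")

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(
            [e for e in self.entries if e.split == split], list(self.class_labels)
        )

    def __len__(self) -> int:
        return len(self.entries)


def read_wav(path: str | Path, *, channel_policy: str = "reject") -> AudioSignal:
    """Read a RIFF/WAVE file into an :class:`AudioSignal`.

    Integer PCM is scaled to [-1, 1] by the type's full-scale value
    (32768 for 16-bit); float WAV is taken as already normalized.

    Parameters
    ----------
    channel_policy : {"reject", "average"}
        What to do with multi-channel files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:  # unsupported encoding (e.g. compressed)
        raise AudioFormatError(f"{path}: not a readable PCM WAV file ({exc})") from exc
    if data.size == 0:
        raise AudioFormatError(f"{path}: zero-length audio")
    if data.ndim == 2 and channel_policy != "average":
        raise AudioFormatError(
            f"{path}: {data.shape[1]} channels; mono required "
            "(pass channel_policy='average' to downmix)"
        )
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / PCM16_FULL_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"{path}: unsupported sample format {data.dtype}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioSignal(samples, int(rate))


def write_wav(path: str | Path, signal: AudioSignal, *, subtype: str = "pcm16") -> None:
    """Write an :class:`AudioSignal` as 16-bit PCM (default) or float32 WAV.

    Samples are clipped to [-1, 1] before quantization.
    """
    clipped = np.clip(signal.samples, -1.0, 1.0)
    if subtype == "pcm16":
        # symmetric scaling matching read_wav; +1.0 saturates at 32767
        pcm = np.clip(np.round(clipped * PCM16_FULL_SCALE), -32768, 32767)
        wavfile.write(str(path), signal.sample_rate, pcm.astype(np.int16))
    elif subtype == "float32":
        wavfile.write(str(path), signal.sample_rate, clipped.astype(np.float32))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")


def resample(signal: AudioSignal, target_rate: int) -> AudioSignal:
    """Anti-aliased polyphase resampling to ``target_rate`` Hz."""
    if target_rate == signal.sample_rate:
        return signal
    frac = Fraction(int(target_rate), int(signal.sample_rate)).limit_denominator(1000)
    out = resample_poly(signal.samples, frac.numerator, frac.denominator)
    return AudioSignal(np.clip(out, -1.0, 1.0), int(target_rate))


def stratified_split(
    manifest: DatasetManifest, train_fraction: float = 0.8, seed: int = 0
) -> DatasetManifest:
    """Tag entries train/test per class: ceil(n * train_fraction) train each.

    Deterministic given ``seed``; preserves entry order and per-class counts.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {lab: [] for lab in manifest.class_labels}
    for i, e in enumerate(manifest.entries):
        by_class[e.label].append(i)
    split_tags = ["test"] * len(manifest.entries)
    for label in manifest.class_labels:
        idx = by_class[label]
        if len(idx) < 2:
            raise ValueError(
                f"class {label!r} has {len(idx)} entries; need >= 2 to stratify"
            )
        n_train = math.ceil(len(idx) * train_fraction)
        order = rng.permutation(len(idx))
        for j in order[:n_train]:
            split_tags[idx[j]] = "train"
    entries = [
        ManifestEntry(e.path, e.label, split_tags[i])
        for i, e in enumerate(manifest.entries)
    ]
    return DatasetManifest(entries, list(manifest.class_labels))


def load_manifest(path: str | Path) -> DatasetManifest:
    """Read a manifest CSV with header ``path,label,split``."""
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "path" not in reader.fieldnames:
            raise ValueError(f"{path}: manifest needs a 'path,label,split' header")
        for row in reader:
            entries.append(
                ManifestEntry(row["path"], row["label"], row.get("split") or "unassigned")
            )
    return DatasetManifest(entries)


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "split"])
        for e in manifest.entries:
            writer.writerow([e.path, e.label, e.split])


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (sections per pipeline stage)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level of the config must be a mapping")
    return cfg
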