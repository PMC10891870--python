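"""End-to-end train/evaluate orchestration.

``run_train`` executes the full recipe on a labeled set of audio clips:
optional Kalman denoising -> optional endpoint detection -> 39-d MFCC
features -> per-class GMM-HMM EM -> Viterbi forced alignment -> state-prior
estimation -> posterior-network training -> hybrid model assembly.
``run_evaluate`` classifies a test set under both the GMM-HMM and the hybrid
DNN-HMM with identical features and reports both confusion matrices and
metrics, plus an optional single-Gaussian ("base HMM", K = 1) ablation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .audio import AudioSignal
from .denoise import KalmanDenoiser
from .endpointing import EndpointConfig, detect_endpoints
from .evaluation import EvalReport, confusion_matrix, metrics
from .features import MFCCExtractor
from .gmm_hmm import GMMHMMClassifier
from .hybrid import DNNHMMClassifier

__all__ = ["RunConfig", "TrainedSystem", "run_train", "run_evaluate"]


@dataclass
class RunConfig:
    """Nested per-stage settings with the recipe defaults."""

    denoise: bool = False
    endpoint: bool = False
    ar_order: int = 12
    n_filters: int = 26
    n_states: int = 5
    n_components: int = 4
    em_max_iter: int = 40
    em_tol: float = 1e-6
    context: int = 3
    hidden: tuple[int, ...] = (128, 128, 128)
    learning_rate: float = 0.003
    batch_size: int = 100
    epochs: int = 10
    max_iter: int = 200
    dnn_tol: float = 1e-6
    val_fraction: float = 0.1
    patience: int = 3
    base_hmm: bool = False  # additionally train the K=1 ablation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 1 or self.n_components < 1:
            raise ValueError("n_states and n_components must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class TrainedSystem:
    gmm_hmm: GMMHMMClassifier
    hybrid: DNNHMMClassifier
    base_hmm: GMMHMMClassifier | None
    feature_extractor: MFCCExtractor
    config: RunConfig
    timings: dict = field(default_factory=dict)


def _front_end(signals: list[AudioSignal], config: RunConfig) -> list[np.ndarray]:
    if config.denoise:
        signals = KalmanDenoiser(ar_order=config.ar_order).fit([]).transform(signals)
    if config.endpoint:
        cropped = []
        for sig in signals:
            segs = detect_endpoints(sig, EndpointConfig())
            if segs:
                lo, hi = segs[0].start, segs[-1].end
                cropped.append(AudioSignal(sig.samples[lo:hi], sig.sample_rate))
            else:
                cropped.append(sig)
        signals = cropped
    return MFCCExtractor(n_filters=config.n_filters).transform(signals)


def run_train(signals: list[AudioSignal], labels, config: RunConfig | None = None,
              expected_classes: list[str] | None = None) -> TrainedSystem:
    """Train the full system from labeled audio clips.

    ``expected_classes`` (e.g. a manifest's class list) makes a class with
    no training clips an explicit error naming the class.
    """
    config = config or RunConfig()
    labels = np.asarray(labels)
    if len(signals) != labels.size:
        raise ValueError("signals and labels length mismatch")
    if labels.size == 0:
        raise ValueError("empty training set")
    if expected_classes is not None:
        missing = [c for c in expected_classes if c not in set(labels.tolist())]
        if missing:
            raise ValueError(f"no training clips for classes: {missing}")
    timings = {}
    t0 = time.perf_counter()
    feats = _front_end(signals, config)
    timings["front_end_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    gmm = GMMHMMClassifier(
        n_states=config.n_states, n_components=config.n_components,
        max_iter=config.em_max_iter, tol=config.em_tol,
        random_state=config.seed,
    ).fit(feats, labels)
    timings["gmm_hmm_s"] = time.perf_counter() - t0

    base = None
    if config.base_hmm:
        t0 = time.perf_counter()
        base = GMMHMMClassifier(
            n_states=config.n_states, n_components=1,
            max_iter=config.em_max_iter, tol=config.em_tol,
            random_state=config.seed,
        ).fit(feats, labels)
        timings["base_hmm_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    hybrid = DNNHMMClassifier(
        gmm_hmm=gmm, context=config.context, hidden=config.hidden,
        learning_rate=config.learning_rate, batch_size=config.batch_size,
        epochs=config.epochs, max_iter=config.max_iter, tol=config.dnn_tol,
        val_fraction=config.val_fraction, patience=config.patience,
        random_state=config.seed,
    ).fit(feats, labels)
    timings["dnn_s"] = time.perf_counter() - t0

    return TrainedSystem(
        gmm_hmm=gmm, hybrid=hybrid, base_hmm=base,
        feature_extractor=MFCCExtractor(n_filters=config.n_filters),
        config=config, timings=timings,
    )


def run_evaluate(system: TrainedSystem, signals: list[AudioSignal], labels
                 ) -> dict[str, EvalReport]:
    """Classify a test set under every trained model; identical features."""
    labels = list(np.asarray(labels))
    feats = _front_end(signals, system.config)
    class_order = [str(c) for c in system.gmm_hmm.classes_]
    reports: dict[str, EvalReport] = {}
    pairs = [("gmm_hmm", system.gmm_hmm), ("dnn_hmm", system.hybrid)]
    if system.base_hmm is not None:
        pairs.append(("base_hmm", system.base_hmm))
    for name, model in pairs:
        pred = [str(p) for p in model.predict(feats)]
        cm = confusion_matrix([str(t) for t in labels], pred, class_order)
        reports[name] = metrics(cm, class_order)
    return reports
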