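"""Hybrid DNN-HMM decoding.

The network outputs state posteriors p(q | x_t) over all class-state units.
HMM decoding needs emission likelihoods, so posteriors are converted to
scaled likelihoods

    log p(x_t | q) = log p(q | x_t) - log p(q)   (+ log p(x_t), dropped)

where p(q) is the state prior estimated from forced-alignment frame counts
with add-one smoothing.  The per-frame p(x_t) term is identical for every
unit and therefore cannot change any decoding decision.  Each class is then
scored by Viterbi over its own left-to-right topology using its units' rows
of the scaled log-likelihood matrix; the predicted class is the argmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .dnn import DNNParams, PROB_FLOOR, FrameLabelSet, TrainConfig, forward, train_dnn
from .features import splice
from .gmm_hmm import Alignment, GMMHMMClassifier

__all__ = [
    "HybridModel",
    "estimate_state_priors",
    "scaled_log_likelihoods",
    "decode",
    "viterbi_scaled",
    "DNNHMMClassifier",
]


@dataclass
class HybridModel:
    """DNN + state priors + per-class HMM topologies.

    Unit indexing is class-major: unit = class_index * n_states + state_index
    with classes ordered as ``class_labels``.
    """

    dnn: DNNParams
    priors: np.ndarray  # (S_out,)
    class_labels: list[str]
    n_states: int
    pis: dict[str, np.ndarray]  # per-class initial distributions
    transes: dict[str, np.ndarray]  # per-class transition matrices

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, float)
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        if np.any(self.priors <= 0):
            raise ValueError("priors must be strictly positive (floored)")
        if self.priors.size != len(self.class_labels) * self.n_states:
            raise ValueError("prior length != n_classes * n_states")

    def unit_index(self, class_index: int, state_index: int) -> int:
        return class_index * self.n_states + state_index


def estimate_state_priors(
    alignments: list[Alignment],
    class_labels: list[str],
    n_states: int,
    smoothing: float = 1.0,
) -> np.ndarray:
    """Add-one-smoothed unit priors from forced-alignment frame counts:
    p(q) = (count_q + delta) / (total + delta * S_out)."""
    if not alignments:
        raise ValueError("empty alignment set")
    s_out = len(class_labels) * n_states
    counts = np.zeros(s_out)
    label_to_idx = {lab: i for i, lab in enumerate(class_labels)}
    for ali in alignments:
        c = label_to_idx[ali.label]
        for s in ali.state_ids:
            counts[c * n_states + int(s)] += 1
    return (counts + smoothing) / (counts.sum() + smoothing * s_out)


def scaled_log_likelihoods(model: HybridModel, spliced: np.ndarray) -> np.ndarray:
    """(T, S_out) matrix of log p(q|x_t) - log p(q), posteriors floored."""
    post = forward(model.dnn, spliced)
    return np.log(np.maximum(post, PROB_FLOOR)) - np.log(model.priors)[None, :]


def viterbi_scaled(log_pi: np.ndarray, log_trans: np.ndarray,
                   log_b: np.ndarray) -> tuple[np.ndarray, float]:
    """Generic log-domain Viterbi over an emission log-likelihood matrix."""
    T, N = log_b.shape
    delta = log_pi + log_b[0]
    back = np.zeros((T, N), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_trans
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(N)] + log_b[t]
    last = int(np.argmax(delta))
    path = np.empty(T, dtype=int)
    path[-1] = last
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, float(delta[last])


def decode(model: HybridModel, spliced: np.ndarray
           ) -> tuple[str, np.ndarray, np.ndarray]:
    """Classify a spliced feature sequence.

    Returns (label, per-class log-scores, best state path of the winning
    class).  Ties break to the first class; all scores -inf yields label ""
    (unclassifiable).
    """
    sllh = scaled_log_likelihoods(model, spliced)
    N = model.n_states
    scores = np.empty(len(model.class_labels))
    paths = []
    for c, label in enumerate(model.class_labels):
        with np.errstate(divide="ignore"):
            log_pi = np.log(model.pis[label])
            log_trans = np.log(model.transes[label])
        path, score = viterbi_scaled(log_pi, log_trans, sllh[:, c * N:(c + 1) * N])
        scores[c] = score
        paths.append(path)
    if np.all(np.isneginf(scores)):
        return "", scores, np.array([], dtype=int)
    best = int(np.argmax(scores))
    return model.class_labels[best], scores, paths[best]


def save_hybrid(model: HybridModel, path: str | Path) -> None:
    payload = {
        "format_version": 1,
        "unit_indexing": "class_major",
        "class_labels": model.class_labels,
        "n_states": model.n_states,
        "priors": model.priors.tolist(),
        "weights": [w.tolist() for w in model.dnn.weights],
        "biases": [b.tolist() for b in model.dnn.biases],
        "pis": {k: v.tolist() for k, v in model.pis.items()},
        "transes": {k: v.tolist() for k, v in model.transes.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_hybrid(path: str | Path) -> HybridModel:
    payload = json.loads(Path(path).read_text())
    dnn = DNNParams([np.array(w) for w in payload["weights"]],
                    [np.array(b) for b in payload["biases"]])
    return HybridModel(
        dnn=dnn, priors=np.array(payload["priors"]),
        class_labels=list(payload["class_labels"]),
        n_states=int(payload["n_states"]),
        pis={k: np.array(v) for k, v in payload["pis"].items()},
        transes={k: np.array(v) for k, v in payload["transes"].items()},
    )


class DNNHMMClassifier(BaseEstimator, ClassifierMixin):
    """End-to-end hybrid classifier over 39-d feature sequences.

    fit(X, y): trains (or reuses) a per-class GMM-HMM system, force-aligns
    every training sequence under its own class model, estimates unit priors
    from the alignments, trains the posterior network on spliced frames, and
    assembles the hybrid decoder.

    Parameters
    ----------
    gmm_hmm : GMMHMMClassifier or None
        A fitted GMM-HMM system to reuse; a fresh one is trained when None.
    context : int
        Splice context (frames each side); input width = D * (2*context+1).
    Remaining parameters mirror GMMHMMClassifier and TrainConfig.

    Attributes
    ----------
    classes_, gmm_hmm_, hybrid_, dnn_history_
    """

    def __init__(self, gmm_hmm: GMMHMMClassifier | None = None,
                 n_states: int = 5, n_components: int = 4,
                 em_max_iter: int = 40, em_tol: float = 1e-6,
                 context: int = 3, hidden: tuple[int, ...] = (128, 128, 128),
                 learning_rate: float = 0.003, batch_size: int = 100,
                 epochs: int = 10, max_iter: int = 200, tol: float = 1e-6,
                 val_fraction: float = 0.1, patience: int = 3,
                 random_state: int = 0):
        self.gmm_hmm = gmm_hmm
        self.n_states = n_states
        self.n_components = n_components
        self.em_max_iter = em_max_iter
        self.em_tol = em_tol
        self.context = context
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.max_iter = max_iter
        self.tol = tol
        self.val_fraction = val_fraction
        self.patience = patience
        self.random_state = random_state

    def fit(self, X: list[np.ndarray], y):
        y = np.asarray(y)
        if self.gmm_hmm is not None:
            check_is_fitted(self.gmm_hmm, "models_")
            self.gmm_hmm_ = self.gmm_hmm
        else:
            self.gmm_hmm_ = GMMHMMClassifier(
                n_states=self.n_states, n_components=self.n_components,
                max_iter=self.em_max_iter, tol=self.em_tol,
                random_state=self.random_state,
            ).fit(X, y)
        self.classes_ = self.gmm_hmm_.classes_
        labels = [str(lab) for lab in self.classes_]
        n_states = self.gmm_hmm_.n_states

        alignments = self.gmm_hmm_.align(X, y)
        priors = estimate_state_priors(alignments, labels, n_states)

        label_to_idx = {lab: i for i, lab in enumerate(labels)}
        spliced_rows = []
        targets = []
        for obs, ali in zip(X, alignments):
            spliced_rows.append(splice(np.asarray(obs, float), self.context))
            c = label_to_idx[ali.label]
            targets.append(c * n_states + ali.state_ids)
        inputs = np.vstack(spliced_rows)
        target_vec = np.concatenate(targets)
        cfg = TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, max_iter=self.max_iter, tol=self.tol,
            val_fraction=self.val_fraction, patience=self.patience,
            seed=self.random_state,
        )
        labelset = FrameLabelSet(inputs, target_vec, len(labels) * n_states)
        params, self.dnn_history_ = train_dnn(labelset, cfg, tuple(self.hidden))

        self.hybrid_ = HybridModel(
            dnn=params, priors=priors, class_labels=labels, n_states=n_states,
            pis={lab: self.gmm_hmm_.models_[self.classes_[i]].pi
                 for i, lab in enumerate(labels)},
            transes={lab: self.gmm_hmm_.models_[self.classes_[i]].trans
                     for i, lab in enumerate(labels)},
        )
        return self

    def decision_function(self, X: list[np.ndarray]) -> np.ndarray:
        check_is_fitted(self, "hybrid_")
        out = []
        for obs in X:
            _, scores, _ = decode(self.hybrid_, splice(np.asarray(obs, float),
                                                       self.context))
            out.append(scores)
        return np.vstack(out)

    def predict(self, X: list[np.ndarray]) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]
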