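"""Feed-forward network mapping spliced MFCC frames to per-(class, state)
posteriors, trained on forced-alignment labels.

Architecture: input (default 273 = 39-d features x 7 spliced frames) ->
three ReLU hidden layers of 128 units -> softmax over all class-state units
(25 for 5 classes x 5 states).  Training minimizes the mean cross-entropy
J_CE = -(1/M) sum_i ln y_{i, target(i)} by back-propagation with Adam
updates, He-normal initialization, shuffled mini-batches and early stopping
on a held-out validation split.

Everything is plain numpy; gradients are exact (softmax + cross-entropy
fused delta at the output, ReLU mask through the hidden layers) and are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DNNParams",
    "TrainConfig",
    "FrameLabelSet",
    "init_params",
    "forward",
    "cross_entropy",
    "backward",
    "train_dnn",
    "StatePosteriorNet",
]

PROB_FLOOR = 1e-12


@dataclass
class DNNParams:
    """Weights and biases per layer; ReLU hidden activations, softmax output."""

    weights: list[np.ndarray]  # W_l: (fan_in, fan_out)
    biases: list[np.ndarray]  # b_l: (fan_out,)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def copy(self) -> "DNNParams":
        return DNNParams([w.copy() for w in self.weights],
                         [b.copy() for b in self.biases])


@dataclass
class TrainConfig:
    learning_rate: float = 0.003
    batch_size: int = 100
    epochs: int = 10
    max_iter: int = 200  # optimizer-step cap per epoch
    tol: float = 1e-6
    val_fraction: float = 0.1
    patience: int = 3  # validation checks without improvement
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class FrameLabelSet:
    """Spliced inputs (M, width) with integer class-state targets in
    [0, n_units); target = class_index * n_states + state_index."""

    inputs: np.ndarray
    targets: np.ndarray
    n_units: int

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, float)
        self.targets = np.asarray(self.targets, int)
        if self.inputs.shape[0] != self.targets.size:
            raise ValueError("inputs and targets length mismatch")
        if np.any(self.targets < 0) or np.any(self.targets >= self.n_units):
            raise ValueError("target outside [0, n_units)")


def init_params(layer_sizes: list[int], seed: int = 0) -> DNNParams:
    """He-normal initialization (std = sqrt(2/fan_in)), zero biases."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        weights.append(rng.standard_normal((fan_in, fan_out))
                       * np.sqrt(2.0 / fan_in))
        biases.append(np.zeros(fan_out))
    return DNNParams(weights, biases)


def _forward_cached(params: DNNParams, batch: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Softmax posteriors plus per-layer activations (for backprop)."""
    acts = [batch]
    a = batch
    L = params.n_layers
    for l in range(L - 1):
        a = np.maximum(a @ params.weights[l] + params.biases[l], 0.0)
        acts.append(a)
    z = a @ params.weights[-1] + params.biases[-1]
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    post = e / e.sum(axis=1, keepdims=True)
    return post, acts


def forward(params: DNNParams, batch: np.ndarray) -> np.ndarray:
    """Posterior matrix (rows sum to 1) for a batch of spliced frames."""
    batch = np.atleast_2d(np.asarray(batch, float))
    if not np.all(np.isfinite(batch)):
        raise ValueError("non-finite input batch")
    if batch.shape[1] != params.weights[0].shape[0]:
        raise ValueError(
            f"input width {batch.shape[1]} != layer-1 width {params.weights[0].shape[0]}")
    post, _ = _forward_cached(params, batch)
    return post


def cross_entropy(posteriors: np.ndarray, targets: np.ndarray) -> float:
    """Mean over the batch of -ln(posterior at the target unit)."""
    posteriors = np.atleast_2d(posteriors)
    targets = np.asarray(targets, int)
    p = np.maximum(posteriors[np.arange(targets.size), targets], PROB_FLOOR)
    return float(-np.mean(np.log(p)))


def backward(params: DNNParams, batch: np.ndarray, targets: np.ndarray
             ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Exact gradients of the mean cross-entropy w.r.t. every W_l and b_l."""
    batch = np.atleast_2d(np.asarray(batch, float))
    targets = np.asarray(targets, int)
    M = batch.shape[0]
    post, acts = _forward_cached(params, batch)
    delta = post.copy()
    delta[np.arange(M), targets] -= 1.0
    delta /= M
    grads_w: list[np.ndarray] = [None] * params.n_layers  # type: ignore[list-item]
    grads_b: list[np.ndarray] = [None] * params.n_layers  # type: ignore[list-item]
    for l in range(params.n_layers - 1, -1, -1):
        grads_w[l] = acts[l].T @ delta
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ params.weights[l].T) * (acts[l] > 0.0)
    return grads_w, grads_b


@dataclass
class _AdamState:
    m_w: list[np.ndarray]
    v_w: list[np.ndarray]
    m_b: list[np.ndarray]
    v_b: list[np.ndarray]
    t: int = 0


def _adam_step(params: DNNParams, grads_w, grads_b, state: _AdamState,
               cfg: TrainConfig) -> None:
    state.t += 1
    b1, b2, eps, lr = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps, cfg.learning_rate
    corr1 = 1.0 - b1**state.t
    corr2 = 1.0 - b2**state.t
    for l in range(params.n_layers):
        for m, v, g, p in ((state.m_w[l], state.v_w[l], grads_w[l], params.weights[l]),
                           (state.m_b[l], state.v_b[l], grads_b[l], params.biases[l])):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g**2
            p -= lr * (m / corr1) / (np.sqrt(v / corr2) + eps)


def _stratified_val_split(targets: np.ndarray, val_fraction: float,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-target-unit split keeping at least one training frame per unit."""
    val_mask = np.zeros(targets.size, dtype=bool)
    for unit in np.unique(targets):
        idx = np.flatnonzero(targets == unit)
        n_val = int(round(idx.size * val_fraction))
        if n_val >= idx.size:
            warnings.warn(f"unit {unit}: validation split would empty it; re-split")
            n_val = idx.size - 1
        if n_val > 0:
            val_mask[rng.permutation(idx)[:n_val]] = True
    return ~val_mask, val_mask


def train_dnn(labelset: FrameLabelSet, config: TrainConfig | None = None,
              hidden: tuple[int, ...] = (128, 128, 128),
              ) -> tuple[DNNParams, dict]:
    """Train the network; returns (best-validation parameters, history).

    History holds per-epoch mean training loss, validation loss and frame
    accuracies.  Stopping: validation loss not improving for ``patience``
    epoch-end checks, relative training-loss change below ``tol``, or the
    epoch cap; each epoch is additionally capped at ``max_iter`` optimizer
    steps.  Fully deterministic given ``config.seed``.
    """
    cfg = config or TrainConfig()
    if np.unique(labelset.targets).size < 2:
        raise ValueError("need at least 2 distinct target units to train")
    rng = np.random.default_rng(cfg.seed)
    train_mask, val_mask = _stratified_val_split(labelset.targets,
                                                 cfg.val_fraction, rng)
    X_tr, y_tr = labelset.inputs[train_mask], labelset.targets[train_mask]
    X_va, y_va = labelset.inputs[val_mask], labelset.targets[val_mask]
    sizes = [labelset.inputs.shape[1], *hidden, labelset.n_units]
    params = init_params(sizes, seed=int(rng.integers(2**31 - 1)))
    adam = _AdamState(
        m_w=[np.zeros_like(w) for w in params.weights],
        v_w=[np.zeros_like(w) for w in params.weights],
        m_b=[np.zeros_like(b) for b in params.biases],
        v_b=[np.zeros_like(b) for b in params.biases],
    )
    history = {"train_loss": [], "val_loss": [], "train_acc": [], "val_acc": []}
    best_params = params.copy()
    best_val = np.inf
    bad_checks = 0
    prev_train_loss = None
    M = X_tr.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(M)
        n_steps = 0
        for start in range(0, M, cfg.batch_size):
            if n_steps >= cfg.max_iter:
                break
            sel = order[start:start + cfg.batch_size]
            gw, gb = backward(params, X_tr[sel], y_tr[sel])
            _adam_step(params, gw, gb, adam, cfg)
            n_steps += 1
        post_tr = forward(params, X_tr)
        train_loss = cross_entropy(post_tr, y_tr)
        train_acc = float(np.mean(post_tr.argmax(axis=1) == y_tr))
        if X_va.shape[0] > 0:
            post_va = forward(params, X_va)
            val_loss = cross_entropy(post_va, y_va)
            val_acc = float(np.mean(post_va.argmax(axis=1) == y_va))
        else:
            val_loss, val_acc = train_loss, train_acc
        if not np.isfinite(train_loss):
            raise FloatingPointError("training diverged (non-finite loss)")
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["train_acc"].append(train_acc)
        history["val_acc"].append(val_acc)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = params.copy()
            bad_checks = 0
        else:
            bad_checks += 1
            if bad_checks >= cfg.patience:
                break
        if prev_train_loss is not None:
            rel = abs(prev_train_loss - train_loss) / (abs(prev_train_loss) + 1e-30)
            if rel < cfg.tol:
                break
        prev_train_loss = train_loss
    return best_params, history


class StatePosteriorNet(BaseEstimator, ClassifierMixin):
    """Sklearn-style wrapper around :func:`train_dnn`.

    fit(X, y): X is an (M, width) array of spliced frames, y integer
    class-state unit targets.  ``predict_proba`` returns the softmax
    posteriors used by the hybrid decoder.
    """

    def __init__(self, hidden: tuple[int, ...] = (128, 128, 128),
                 learning_rate: float = 0.003, batch_size: int = 100,
                 epochs: int = 10, max_iter: int = 200, tol: float = 1e-6,
                 val_fraction: float = 0.1, patience: int = 3,
                 random_state: int = 0):
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.max_iter = max_iter
        self.tol = tol
        self.val_fraction = val_fraction
        self.patience = patience
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray):
        y = np.asarray(y, int)
        n_units = int(y.max()) + 1
        cfg = TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, max_iter=self.max_iter, tol=self.tol,
            val_fraction=self.val_fraction, patience=self.patience,
            seed=self.random_state,
        )
        labelset = FrameLabelSet(np.asarray(X, float), y, n_units)
        self.params_, self.history_ = train_dnn(labelset, cfg, tuple(self.hidden))
        self.classes_ = np.arange(n_units)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "params_")
        return forward(self.params_, np.asarray(X, float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)
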