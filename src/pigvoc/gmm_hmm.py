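"""Left-to-right GMM-HMMs: initialization, Baum-Welch EM, Viterbi decoding,
forced alignment and whole-segment classification.

One HMM per vocalization class.  Topology: N states (default 5), initial
distribution pi = [1, 0, ..., 0], each state self-loops or advances to the
next state (upper-bidiagonal transition matrix, last state absorbing).
Emissions are diagonal-covariance Gaussian mixtures (K components per state,
default 4).  All trellis arithmetic is in the log domain.

EM re-estimation accumulates numerators and denominators over all training
sequences before dividing (multi-sequence Baum-Welch); the zero structure of
the left-to-right transition matrix is preserved because a zero transition
contributes zero expected counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ClassHMM",
    "TrellisResult",
    "Alignment",
    "init_model",
    "forward_backward",
    "baum_welch",
    "viterbi",
    "classify",
    "sample_sequence",
    "save_model",
    "load_model",
    "GMMHMMClassifier",
]

VAR_FLOOR = 1e-3
LOG_ZERO = -np.inf


@dataclass
class ClassHMM:
    """Left-to-right HMM with diagonal-covariance GMM emissions.

    weights: (N, K); means: (N, K, D); variances: (N, K, D).
    """

    pi: np.ndarray
    trans: np.ndarray
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, float)
        self.trans = np.asarray(self.trans, float)
        self.weights = np.asarray(self.weights, float)
        self.means = np.asarray(self.means, float)
        self.variances = np.asarray(self.variances, float)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.pi.size

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def dim(self) -> int:
        return self.means.shape[2]

    def validate(self) -> None:
        N, K = self.weights.shape
        if self.pi.shape != (N,) or self.trans.shape != (N, N):
            raise ValueError("inconsistent HMM shapes")
        if self.means.shape[:2] != (N, K) or self.variances.shape != self.means.shape:
            raise ValueError("inconsistent emission shapes")
        if not np.allclose(self.trans.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("mixture weights must sum to 1 per state")
        if np.any(self.variances < VAR_FLOOR - 1e-12):
            raise ValueError("variance below floor")


@dataclass
class TrellisResult:
    log_alpha: np.ndarray  # (T, N)
    log_beta: np.ndarray  # (T, N)
    log_likelihood: float
    gamma: np.ndarray  # (T, N)
    gamma_mix: np.ndarray  # (T, N, K)
    xi: np.ndarray  # (T-1, N, N)


@dataclass
class Alignment:
    state_ids: np.ndarray
    log_score: float
    label: str = ""


def _log_gauss_mix(model: ClassHMM, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame log emission terms.

    Returns ``log_comp`` (T, N, K): log(c_jk) + log N(o_t; mu_jk, Sigma_jk),
    and ``log_b`` (T, N): logsumexp over components.
    """
    obs = np.asarray(obs, float)
    diff = obs[:, None, None, :] - model.means[None]  # (T, N, K, D)
    inv_var = 1.0 / model.variances
    quad = np.einsum("tnkd,nkd->tnk", diff**2, inv_var)
    log_det = np.sum(np.log(model.variances), axis=2)  # (N, K)
    D = model.dim
    log_norm = -0.5 * (D * np.log(2.0 * np.pi) + log_det)  # (N, K)
    with np.errstate(divide="ignore"):
        log_w = np.log(model.weights)
    log_comp = log_w[None] + log_norm[None] - 0.5 * quad  # (T, N, K)
    log_b = logsumexp(log_comp, axis=2)
    return log_comp, log_b


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    """logsumexp tolerant of all-(-inf) slices, minimal overhead."""
    m = np.max(a, axis=axis)
    finite = np.isfinite(m)
    out = np.full(m.shape, LOG_ZERO)
    if np.all(finite):
        return m + np.log(np.sum(np.exp(a - np.expand_dims(m, axis)), axis=axis))
    if np.any(finite):
        shifted = np.exp(a - np.expand_dims(np.where(finite, m, 0.0), axis))
        s = np.sum(shifted, axis=axis)
        out[finite] = m[finite] + np.log(s[finite])
    return out


def _log_forward(log_pi, log_trans, log_b):
    T, N = log_b.shape
    log_alpha = np.full((T, N), LOG_ZERO)
    log_alpha[0] = log_pi + log_b[0]
    for t in range(1, T):
        log_alpha[t] = _lse(log_alpha[t - 1][:, None] + log_trans, 0) + log_b[t]
    return log_alpha


def _log_backward(log_trans, log_b):
    T, N = log_b.shape
    log_beta = np.zeros((T, N))
    for t in range(T - 2, -1, -1):
        log_beta[t] = _lse(log_trans + (log_b[t + 1] + log_beta[t + 1])[None, :], 1)
    return log_beta


def forward_backward(model: ClassHMM, obs: np.ndarray) -> TrellisResult:
    """Log-domain forward-backward with state, pair and component posteriors."""
    obs = np.asarray(obs, float)
    if not np.all(np.isfinite(obs)):
        raise ValueError("observations must be finite")
    log_comp, log_b = _log_gauss_mix(model, obs)
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi)
        log_trans = np.log(model.trans)
    log_alpha = _log_forward(log_pi, log_trans, log_b)
    log_beta = _log_backward(log_trans, log_b)
    ll = float(logsumexp(log_alpha[-1]))
    if not np.isfinite(ll):
        raise FloatingPointError("sequence impossible under the model (loglik -inf)")
    log_gamma = log_alpha + log_beta - ll
    gamma = np.exp(log_gamma)
    # component posteriors: gamma_t(j) * responsibilities within state j
    log_resp = log_comp - log_b[:, :, None]
    gamma_mix = gamma[:, :, None] * np.exp(log_resp)
    T = obs.shape[0]
    xi = np.zeros((max(T - 1, 0), model.n_states, model.n_states))
    for t in range(T - 1):
        m = (log_alpha[t][:, None] + log_trans
             + (log_b[t + 1] + log_beta[t + 1])[None, :] - ll)
        xi[t] = np.exp(m)
    return TrellisResult(log_alpha, log_beta, ll, gamma, gamma_mix, xi)


def init_model(
    features_for_class: list[np.ndarray],
    n_states: int = 5,
    n_components: int = 4,
    label: str = "",
    seed: int = 0,
    var_floor: float = VAR_FLOOR,
) -> ClassHMM:
    """Flat-start initialization: each sequence is split into ``n_states``
    equal-duration blocks; state j's GMM is estimated from the pooled frames
    of block j, with component k seeded from the k-th temporal sub-block.

    ``seed`` is accepted for interface stability but the procedure is fully
    deterministic."""
    usable = []
    for fm in features_for_class:
        if fm.shape[0] < n_states:
            warnings.warn(f"sequence with {fm.shape[0]} < {n_states} frames skipped")
            continue
        usable.append(np.asarray(fm, float))
    if not usable:
        raise ValueError("no training sequence has at least n_states frames")
    D = usable[0].shape[1]
    # pool per (state, component): state j <- j-th of N equal-duration
    # blocks; component k <- k-th of K equal sub-blocks within it.  Fully
    # deterministic and invariant under duplicating training sequences.
    pools: list[list[list[np.ndarray]]] = [
        [[] for _ in range(n_components)] for _ in range(n_states)
    ]
    for fm in usable:
        edges = np.linspace(0, fm.shape[0], n_states + 1).round().astype(int)
        for j in range(n_states):
            block = fm[edges[j]:edges[j + 1]]
            sub = np.linspace(0, block.shape[0], n_components + 1).round().astype(int)
            for k in range(n_components):
                pools[j][k].append(block[sub[k]:sub[k + 1]])
    weights = np.zeros((n_states, n_components))
    means = np.zeros((n_states, n_components, D))
    variances = np.ones((n_states, n_components, D))
    for j in range(n_states):
        state_frames = np.vstack([f for k in range(n_components)
                                  for f in pools[j][k]])
        state_mean = state_frames.mean(axis=0)
        state_var = np.maximum(state_frames.var(axis=0), var_floor)
        n_state = state_frames.shape[0]
        for k in range(n_components):
            frames = np.vstack(pools[j][k]) if pools[j][k] else np.empty((0, D))
            if frames.shape[0] < 2:
                means[j, k] = state_mean
                variances[j, k] = state_var
                weights[j, k] = 1.0
            else:
                means[j, k] = frames.mean(axis=0)
                variances[j, k] = np.maximum(frames.var(axis=0), var_floor)
                weights[j, k] = frames.shape[0] / n_state
        weights[j] /= weights[j].sum()
    pi = np.zeros(n_states)
    pi[0] = 1.0
    trans = np.zeros((n_states, n_states))
    for i in range(n_states - 1):
        trans[i, i] = 0.5
        trans[i, i + 1] = 0.5
    trans[-1, -1] = 1.0
    return ClassHMM(pi, trans, weights, means, variances, label)


def baum_welch(
    model: ClassHMM,
    training_set: list[np.ndarray],
    max_iter: int = 40,
    tol: float = 1e-6,
    var_floor: float = VAR_FLOOR,
) -> tuple[ClassHMM, list[float]]:
    """Multi-sequence Baum-Welch EM.

    Numerators/denominators are summed over sequences before dividing.
    Stops when the relative total log-likelihood improvement drops below
    ``tol`` or at ``max_iter``.  Returns the trained model and the per-
    iteration total log-likelihood history (non-decreasing up to float
    round-off).
    """
    if not training_set:
        raise ValueError("empty training set")
    N, K, D = model.n_states, model.n_components, model.dim
    history: list[float] = []
    current = model
    for _ in range(max_iter):
        trans_num = np.zeros((N, N))
        gamma_state_sum = np.zeros(N)  # sum over t=1..T-1 of gamma (trans denom)
        occ = np.zeros((N, K))  # sum_c sum_t gamma_mix
        mean_num = np.zeros((N, K, D))
        var_num = np.zeros((N, K, D))
        total_ll = 0.0
        for obs in training_set:
            tr = forward_backward(current, obs)
            total_ll += tr.log_likelihood
            trans_num += tr.xi.sum(axis=0)
            gamma_state_sum += tr.gamma[:-1].sum(axis=0)
            occ += tr.gamma_mix.sum(axis=0)
            mean_num += np.einsum("tnk,td->nkd", tr.gamma_mix, obs)
            var_num += np.einsum("tnk,td->nkd", tr.gamma_mix, np.asarray(obs) ** 2)
        history.append(total_ll)

        trans = current.trans.copy()
        for i in range(N):
            if gamma_state_sum[i] > 1e-12:
                row = trans_num[i] / gamma_state_sum[i]
                s = row.sum()
                if s > 0:
                    trans[i] = row / s
        weights = current.weights.copy()
        means = current.means.copy()
        variances = current.variances.copy()
        for j in range(N):
            state_occ = occ[j].sum()
            for k in range(K):
                if occ[j, k] > 1e-10:
                    means[j, k] = mean_num[j, k] / occ[j, k]
                    ex2 = var_num[j, k] / occ[j, k]
                    variances[j, k] = np.maximum(ex2 - means[j, k] ** 2, var_floor)
                else:
                    warnings.warn(
                        f"state {j} component {k}: empty occupancy, parameters kept")
            if state_occ > 1e-10:
                w = occ[j] / state_occ
                w = np.maximum(w, 1e-8)
                weights[j] = w / w.sum()
        current = ClassHMM(current.pi, trans, weights, means, variances, current.label)
        if len(history) >= 2:
            prev = history[-2]
            rel = abs(history[-1] - prev) / (abs(prev) + 1e-30)
            if rel < tol:
                break
    return current, history


def viterbi(model: ClassHMM, obs: np.ndarray) -> Alignment:
    """Max-product state path in the log domain; ties break toward the lower
    state index (argmax scans predecessors in ascending order)."""
    obs = np.asarray(obs, float)
    _, log_b = _log_gauss_mix(model, obs)
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi)
        log_trans = np.log(model.trans)
    T, N = log_b.shape
    delta = log_pi + log_b[0]
    back = np.zeros((T, N), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_trans  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(N)] + log_b[t]
    last = int(np.argmax(delta))
    score = float(delta[last])
    path = np.empty(T, dtype=int)
    path[-1] = last
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return Alignment(path, score, model.label)


def classify(
    models: list[ClassHMM], obs: np.ndarray, scoring: str = "viterbi"
) -> tuple[str, np.ndarray]:
    """Score ``obs`` under every class model and return (label, scores).

    ``scoring`` is "viterbi" (best-path log score) or "forward" (full
    log-likelihood).  Ties break to the first model; all scores -inf yields
    label "" (unclassifiable).
    """
    if len(models) < 2:
        raise ValueError("need at least 2 class models")
    scores = np.empty(len(models))
    for i, m in enumerate(models):
        if scoring == "viterbi":
            scores[i] = viterbi(m, obs).log_score
        elif scoring == "forward":
            try:
                scores[i] = forward_backward(m, obs).log_likelihood
            except FloatingPointError:
                scores[i] = LOG_ZERO
        else:
            raise ValueError(f"unknown scoring {scoring!r}")
    if np.all(np.isneginf(scores)):
        return "", scores
    return models[int(np.argmax(scores))].label, scores


def sample_sequence(model: ClassHMM, T: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (observations, state path) of length T from the model."""
    states = np.empty(T, dtype=int)
    obs = np.empty((T, model.dim))
    s = rng.choice(model.n_states, p=model.pi)
    for t in range(T):
        states[t] = s
        k = rng.choice(model.n_components, p=model.weights[s])
        obs[t] = model.means[s, k] + np.sqrt(model.variances[s, k]) * rng.standard_normal(model.dim)
        s = rng.choice(model.n_states, p=model.trans[s])
    return obs, states


FORMAT_VERSION = 1


def save_model(model: ClassHMM, path: str | Path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "label": model.label,
        "n_states": model.n_states,
        "n_components": model.n_components,
        "dim": model.dim,
        "pi": model.pi.tolist(),
        "trans": model.trans.tolist(),
        "weights": model.weights.tolist(),
        "means": model.means.tolist(),
        "variances": model.variances.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ClassHMM:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model format {payload.get('format_version')}")
    return ClassHMM(
        np.array(payload["pi"]), np.array(payload["trans"]),
        np.array(payload["weights"]), np.array(payload["means"]),
        np.array(payload["variances"]), payload["label"],
    )


class GMMHMMClassifier(BaseEstimator, ClassifierMixin):
    """Whole-segment classifier: one left-to-right GMM-HMM per class.

    Parameters
    ----------
    n_states : int
        HMM states per class (temporal stages of a vocalization).
    n_components : int
        Gaussians per state.
    max_iter, tol : EM schedule.
    scoring : {"viterbi", "forward"}
        Per-class segment score used at prediction time.
    random_state : int
        Seeds the k-means used in flat-start initialization.

    Attributes
    ----------
    classes_ : ndarray of label strings, in first-seen order.
    models_ : dict label -> ClassHMM.
    history_ : dict label -> per-iteration log-likelihood list.
    """

    def __init__(self, n_states: int = 5, n_components: int = 4,
                 max_iter: int = 40, tol: float = 1e-6,
                 scoring: str = "viterbi", random_state: int = 0):
        self.n_states = n_states
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.scoring = scoring
        self.random_state = random_state

    def fit(self, X: list[np.ndarray], y):
        y = np.asarray(y)
        if len(X) != y.size:
            raise ValueError("X and y length mismatch")
        labels = list(dict.fromkeys(y.tolist()))
        self.classes_ = np.asarray(labels)
        self.models_ = {}
        self.history_ = {}
        for label in labels:
            seqs = [np.asarray(X[i], float) for i in np.flatnonzero(y == label)]
            model = init_model(seqs, self.n_states, self.n_components,
                               label=str(label), seed=self.random_state)
            model, hist = baum_welch(model, seqs, self.max_iter, self.tol)
            self.models_[label] = model
            self.history_[label] = hist
        return self

    def _model_list(self) -> list[ClassHMM]:
        return [self.models_[lab] for lab in self.classes_]

    def decision_function(self, X: list[np.ndarray]) -> np.ndarray:
        check_is_fitted(self, "models_")
        return np.vstack([classify(self._model_list(), obs, self.scoring)[1]
                          for obs in X])

    def predict(self, X: list[np.ndarray]) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def align(self, X: list[np.ndarray], y) -> list[Alignment]:
        """Forced alignment of each sequence under its own class's model."""
        check_is_fitted(self, "models_")
        return [viterbi(self.models_[label], obs) for obs, label in zip(X, y)]
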