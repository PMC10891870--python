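"""Kalman-filter noise reduction for vocalization recordings.

The filter is the classic autoregressive (AR) formulation of Kalman speech
enhancement: the clean signal within each short frame is modelled as an
order-``p`` AR process, the state vector holds the last ``p`` clean samples,
and each noisy sample is treated as a scalar observation of the newest state
entry.  The state-space model is refit per frame so the filter tracks the
nonstationary spectrum of a vocalization, while the measurement-noise
variance ``R`` reflects the (approximately stationary) background noise.

State-space model::

    x_k = A x_{k-1} + w_k,   w_k ~ N(0, Q),  Q = diag(sigma_e^2, 0, ..., 0)
    z_k = H x_k + v_k,       v_k ~ N(0, R),  H = [1, 0, ..., 0]

with ``A`` the companion matrix of the AR coefficients.  Predict/update:

    x(k|k-1) = A x(k-1|k-1)
    P(k|k-1) = A P(k-1|k-1) A' + Q
    g_k      = P(k|k-1) H' / (H P(k|k-1) H' + R)
    x(k|k)   = x(k|k-1) + g_k (z_k - H x(k|k-1))
    P(k|k)   = (I - g_k H) P(k|k-1)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_toeplitz
from sklearn.base import BaseEstimator, TransformerMixin

from .audio import AudioSignal

__all__ = [
    "StateSpaceModel",
    "KalmanState",
    "fit_ar_state_model",
    "kalman_step",
    "kalman_filter_frame",
    "estimate_noise_variance",
    "denoise_signal",
    "snr_db",
    "KalmanDenoiser",
]


@dataclass
class StateSpaceModel:
    """AR companion-form state-space model for one analysis frame."""

    A: np.ndarray  # (p, p) companion matrix; first row = AR coefficients
    H: np.ndarray  # (p,) observation row, e1
    Q: np.ndarray  # (p, p) process-noise covariance, diag(sigma_e^2, 0, ...)
    R: float  # measurement-noise variance
    order: int
    degenerate: bool = False  # all-zero / constant frame


@dataclass
class KalmanState:
    x_est: np.ndarray  # (p,) state estimate
    P: np.ndarray  # (p, p) estimate covariance
    g: np.ndarray | None = None  # last Kalman gain


def _yule_walker(frame: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """AR coefficients and residual variance via the autocorrelation method."""
    n = frame.size
    r = np.array(
        [frame[: n - k] @ frame[k:] for k in range(order + 1)], dtype=np.float64
    )
    r /= n
    if r[0] <= 0.0:
        raise np.linalg.LinAlgError("zero-power frame")
    coeffs = solve_toeplitz((r[:order], r[:order]), r[1 : order + 1])
    sigma2 = float(r[0] - coeffs @ r[1 : order + 1])
    return coeffs, max(sigma2, 0.0)


def fit_ar_state_model(
    frame: np.ndarray, order: int, noise_variance: float
) -> StateSpaceModel:
    """Fit an order-``p`` AR model to ``frame`` and build the companion-form
    state-space model with ``R = noise_variance``.

    Falls back to order 1 (with a warning) if the autocorrelation system is
    singular; an (almost) constant-zero frame yields a degenerate random-walk
    model with zero process noise.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size < 4 * order:
        raise ValueError(f"frame of {frame.size} samples too short for AR order {order}")
    degenerate = False
    try:
        coeffs, sigma2 = _yule_walker(frame, order)
        if not np.all(np.isfinite(coeffs)):
            raise np.linalg.LinAlgError("non-finite AR solution")
    except np.linalg.LinAlgError:
        if np.allclose(frame, 0.0):
            coeffs, sigma2, degenerate = np.zeros(order), 0.0, True
        else:
            warnings.warn("singular autocorrelation system; falling back to AR(1)")
            c1, sigma2 = _yule_walker(frame, 1)
            coeffs = np.zeros(order)
            coeffs[0] = c1[0]
    # mild stabilization: shrink an explosive fit toward zero
    poles = np.roots(np.concatenate(([1.0], -coeffs))) if order > 0 else np.array([])
    if poles.size and np.max(np.abs(poles)) >= 1.0:
        coeffs = coeffs * (0.98 / np.max(np.abs(poles)))
    A = np.zeros((order, order))
    A[0, :] = coeffs
    if order > 1:
        A[1:, :-1] = np.eye(order - 1)
    H = np.zeros(order)
    H[0] = 1.0
    Q = np.zeros((order, order))
    Q[0, 0] = sigma2
    return StateSpaceModel(A=A, H=H, Q=Q, R=float(noise_variance), order=order,
                           degenerate=degenerate)


def kalman_step(
    model: StateSpaceModel, state: KalmanState, z: float
) -> tuple[KalmanState, float]:
    """One predict/update cycle; returns the new state and the filtered sample."""
    x_pred = model.A @ state.x_est
    P_pred = model.A @ state.P @ model.A.T + model.Q
    P_pred = 0.5 * (P_pred + P_pred.T)
    innovation = z - model.H @ x_pred
    if not np.isfinite(innovation):
        warnings.warn("non-finite innovation; resetting to prediction")
        return KalmanState(x_pred, P_pred, state.g), float(model.H @ x_pred)
    s = float(model.H @ P_pred @ model.H + model.R)
    if s <= 0.0:
        gain = np.zeros(model.order)
    else:
        gain = (P_pred @ model.H) / s
    x_new = x_pred + gain * innovation
    P_new = (np.eye(model.order) - np.outer(gain, model.H)) @ P_pred
    P_new = 0.5 * (P_new + P_new.T)
    return KalmanState(x_new, P_new, gain), float(model.H @ x_new)


def kalman_filter_frame(
    model: StateSpaceModel, state: KalmanState, frame: np.ndarray
) -> tuple[KalmanState, np.ndarray]:
    """Run ``kalman_step`` over a whole frame (vectorized inner loop)."""
    out = np.empty(frame.size)
    # unrolled copies of kalman_step, kept in sync, to avoid per-sample
    # dataclass allocation on long signals
    x, P = state.x_est, state.P
    A, H0_row, Q, R, p = model.A, model.H, model.Q, model.R, model.order
    gain = state.g
    eye = np.eye(p)
    for i, z in enumerate(frame):
        x = A @ x
        P = A @ P @ A.T + Q
        s = P[0, 0] + R
        if s <= 0.0:
            gain = np.zeros(p)
        else:
            gain = P[:, 0] / s
        x = x + gain * (z - x[0])
        P = P - np.outer(gain, P[0, :])
        P = 0.5 * (P + P.T)
        out[i] = x[0]
    return KalmanState(x, P, gain), out


def estimate_noise_variance(
    signal: AudioSignal, frame_len_s: float = 0.020, fraction: float = 0.05
) -> float:
    """Minimum-statistics noise estimate: mean power of the lowest-energy
    ``fraction`` of frames."""
    flen = max(int(round(frame_len_s * signal.sample_rate)), 8)
    n_frames = max(signal.samples.size // flen, 1)
    frames = signal.samples[: n_frames * flen].reshape(n_frames, flen)
    powers = np.mean(frames**2, axis=1)
    k = max(int(np.ceil(fraction * n_frames)), 1)
    return float(np.mean(np.sort(powers)[:k]))


def denoise_signal(
    signal: AudioSignal,
    frame_len_s: float = 0.020,
    ar_order: int = 12,
    noise_variance: float | None = None,
) -> AudioSignal:
    """Frame-wise AR refit + sample-wise Kalman filtering of a recording.

    ``noise_variance`` (the measurement variance R) defaults to the
    minimum-statistics estimate from the signal itself.
    """
    x = signal.samples
    if noise_variance is None:
        noise_variance = estimate_noise_variance(signal, frame_len_s)
    flen = int(round(frame_len_s * signal.sample_rate))
    flen = min(max(flen, 4 * ar_order), x.size)
    order = ar_order if flen >= 4 * ar_order else max(flen // 4, 1)
    state = KalmanState(x_est=np.zeros(order), P=np.eye(order) * 1e-2)
    out = np.empty_like(x)
    model: StateSpaceModel | None = None
    for start in range(0, x.size, flen):
        frame = x[start : start + flen]
        if frame.size < 4 * order:
            if model is None:
                out[start : start + frame.size] = frame  # too short to model
                continue
            # trailing stub: reuse the previous frame's model
            state, filt = kalman_filter_frame(model, state, frame)
            out[start : start + frame.size] = filt
            continue
        model = fit_ar_state_model(frame, order, noise_variance)
        state, filt = kalman_filter_frame(model, state, frame)
        out[start : start + frame.size] = filt
    return AudioSignal(np.clip(out, -1.0, 1.0), signal.sample_rate)


def snr_db(clean: AudioSignal | np.ndarray, test: AudioSignal | np.ndarray,
           ceiling_db: float = 100.0) -> float:
    """Signal-to-noise ratio 10*log10(sum(clean^2) / sum((test-clean)^2)) in dB.

    A zero residual returns ``ceiling_db``; an all-zero clean reference is an
    error.
    """
    c = clean.samples if isinstance(clean, AudioSignal) else np.asarray(clean, float)
    t = test.samples if isinstance(test, AudioSignal) else np.asarray(test, float)
    if c.size != t.size:
        raise ValueError("clean and test signals must have equal length")
    p_sig = float(np.sum(c**2))
    if p_sig == 0.0:
        raise ValueError("all-zero clean reference")
    p_res = float(np.sum((t - c) ** 2))
    if p_res == 0.0:
        return ceiling_db
    return min(10.0 * np.log10(p_sig / p_res), ceiling_db)


class KalmanDenoiser(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer applying AR-Kalman denoising to audio.

    Parameters
    ----------
    frame_len_s : float
        Analysis frame length for the AR refit, seconds.
    ar_order : int
        AR model order (12 suits speech-band content at 16-44.1 kHz).
    noise_variance : float or None
        Measurement-noise variance R; estimated per signal when None.

    Attributes
    ----------
    noise_variance_ : float
        R used for the last fitted reference (only set when `fit` is given a
        noise-only reference signal).
    """

    def __init__(self, frame_len_s: float = 0.020, ar_order: int = 12,
                 noise_variance: float | None = None):
        self.frame_len_s = frame_len_s
        self.ar_order = ar_order
        self.noise_variance = noise_variance

    def fit(self, X, y=None, noise_reference: AudioSignal | None = None):
        if noise_reference is not None:
            self.noise_variance_ = float(np.var(noise_reference.samples))
        elif self.noise_variance is not None:
            self.noise_variance_ = float(self.noise_variance)
        else:
            self.noise_variance_ = None
        return self

    def transform(self, X: list[AudioSignal]) -> list[AudioSignal]:
        r = getattr(self, "noise_variance_", self.noise_variance)
        return [
            denoise_signal(sig, self.frame_len_s, self.ar_order, r) for sig in X
        ]
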