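"""Sliding-window stochastic-gradient fitting of a linear-nonlinear-Poisson
population model with functional coupling.

Per neuron *i* and frame *t*, the spike count is Poisson with rate

    rate_i(t) = exp( b_i + K_i . s_t + sum_l H_il y_i(t-l) + sum_j W_ij y_j(t-1) )

with four additive drive terms: a baseline log-rate ``b``, a weight per
stimulus direction ``K`` (8-dim one-hot stimulus indicator, all-zero while
the stimulus is stationary), a self-history filter ``H`` over the previous
1..4 frames, and pairwise coupling ``W`` to every other neuron's previous
frame (diag(W) = 0 — self-effects live in ``H``).

Fitting is online: a ring buffer keeps the last ``window`` (10-100) frames
plus 4 frames of history context, and each new frame triggers one gradient
ascent step on the window's Poisson log-likelihood (the log y! constant is
dropped; it has no gradient).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "LNPParams",
    "LNPWindow",
    "LNPFitter",
    "N_STIM",
    "N_LAGS",
    "lnp_init",
    "lnp_rate",
    "lnp_loglik",
    "lnp_gradient",
    "lnp_sgd_step",
    "lnp_fit_offline",
    "top_connections",
]

N_STIM = 8
N_LAGS = 4
_CLIP = 30.0  # cap on the linear drive: rates saturate at exp(30)


@dataclass
class LNPParams:
    b: np.ndarray  # (n,) baseline log-rates
    K: np.ndarray  # (n, 8) stimulus weights
    H: np.ndarray  # (n, 4) self-history weights, lags 1..4
    W: np.ndarray  # (n, n) coupling, zero diagonal
    step: float = 1e-5

    @property
    def n(self) -> int:
        return self.b.shape[0]

    def copy(self) -> "LNPParams":
        return LNPParams(
            b=self.b.copy(), K=self.K.copy(), H=self.H.copy(), W=self.W.copy(),
            step=self.step,
        )


def lnp_init(n: int, step: float = 1e-5) -> LNPParams:
    return LNPParams(
        b=np.zeros(n), K=np.zeros((n, N_STIM)), H=np.zeros((n, N_LAGS)),
        W=np.zeros((n, n)), step=step,
    )


class LNPWindow:
    """Ring buffer of the most recent frames of (spikes, stimulus) pairs.

    Keeps ``window`` frames for the likelihood plus ``N_LAGS`` extra frames
    of history context; frames before the stream start are treated as silent.
    """

    def __init__(self, n: int, window: int = 100):
        if not (10 <= window <= 100):
            raise ValueError("window length must be in [10, 100] frames")
        self.n = n
        self.window = window
        self._frames: deque[tuple[np.ndarray, np.ndarray]] = deque(
            maxlen=window + N_LAGS
        )

    def push(self, spikes: np.ndarray, stim: np.ndarray) -> None:
        spikes = np.asarray(spikes, dtype=float).ravel()
        stim = np.asarray(stim, dtype=float).ravel()
        if spikes.shape[0] != self.n or stim.shape[0] != N_STIM:
            raise ValueError("frame dimension mismatch")
        self._frames.append((spikes, stim))

    def __len__(self) -> int:
        return min(len(self._frames), self.window)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, int]:
        """(spikes (T,n), stim (T,8), w0) with likelihood frames at [w0:]."""
        T = len(self._frames)
        S = np.zeros((T, self.n))
        X = np.zeros((T, N_STIM))
        for t, (sp, st) in enumerate(self._frames):
            S[t] = sp
            X[t] = st
        w0 = max(0, T - self.window)
        return S, X, w0


def lnp_rate(
    params: LNPParams,
    s_t: np.ndarray,
    y_hist: np.ndarray,
    y_prev: np.ndarray,
) -> np.ndarray:
    """Per-neuron Poisson rate for one frame.

    ``y_hist`` is (n, 4): each neuron's own counts at lags 1..4; ``y_prev``
    is the previous frame's population counts (lag-1, used by the coupling).
    """
    drive = (
        params.b
        + params.K @ np.asarray(s_t, dtype=float)
        + np.sum(params.H * np.asarray(y_hist, dtype=float), axis=1)
        + params.W @ np.asarray(y_prev, dtype=float)
    )
    return np.exp(np.minimum(drive, _CLIP))


def _lagged(S: np.ndarray, lag: int) -> np.ndarray:
    """S shifted down by ``lag`` frames, zero-padded at the stream start."""
    out = np.zeros_like(S)
    if lag < S.shape[0]:
        out[lag:] = S[:-lag]
    return out


def _drives(params: LNPParams, S: np.ndarray, X: np.ndarray, w0: int) -> np.ndarray:
    """Linear drive eta (T-w0, n) for each likelihood frame of the window."""
    eta = params.b[None, :] + X[w0:] @ params.K.T
    for lag in range(1, N_LAGS + 1):
        eta += _lagged(S, lag)[w0:] * params.H[:, lag - 1][None, :]
    eta += _lagged(S, 1)[w0:] @ params.W.T
    return eta


def lnp_loglik(params: LNPParams, window: LNPWindow) -> float:
    """Poisson log-likelihood sum_{t,i} [y log(rate) - rate] over the window
    (the log y! term is dropped)."""
    if len(window) == 0:
        raise ValueError("empty window")
    S, X, w0 = window.arrays()
    eta = np.minimum(_drives(params, S, X, w0), _CLIP)
    Y = S[w0:]
    return float(np.sum(Y * eta - np.exp(eta)))


def lnp_gradient(params: LNPParams, window: LNPWindow) -> LNPParams:
    """Analytic gradient of :func:`lnp_loglik` in parameter layout."""
    S, X, w0 = window.arrays()
    T, n = S.shape
    eta = np.minimum(_drives(params, S, X, w0), _CLIP)
    R = S[w0:] - np.exp(eta)  # (Tw, n) residuals y - rate
    db = R.sum(axis=0)
    dK = R.T @ X[w0:]
    dH = np.empty_like(params.H)
    for lag in range(1, N_LAGS + 1):
        dH[:, lag - 1] = np.sum(R * _lagged(S, lag)[w0:], axis=0)
    dW = R.T @ _lagged(S, 1)[w0:]
    np.fill_diagonal(dW, 0.0)
    return LNPParams(b=db, K=dK, H=dH, W=dW, step=params.step)


def lnp_sgd_step(
    params: LNPParams, window: LNPWindow, step: float | None = None, log=None
) -> LNPParams:
    """One gradient-ascent step on the window log-likelihood.

    Non-finite gradients skip the step (logged) rather than corrupting the
    parameters; the coupling diagonal is re-zeroed after every update.
    """
    if not (10 <= len(window) <= 100):
        raise ValueError("window must hold 10-100 frames")
    step = params.step if step is None else step
    g = lnp_gradient(params, window)
    finite = all(
        np.all(np.isfinite(a)) for a in (g.b, g.K, g.H, g.W)
    )
    if not finite:
        if log is not None:
            log("lnp-skip", "non-finite gradient; step skipped")
        return params
    params.b += step * g.b
    params.K += step * g.K
    params.H += step * g.H
    params.W += step * g.W
    np.fill_diagonal(params.W, 0.0)
    return params


class LNPFitter:
    """Convenience wrapper for streaming LNP fitting: one window push and
    one ascent step per incoming frame.

    ``adaptive=True`` (default) rescales each parameter's step by the
    inverse root of its accumulated squared gradient (Adagrad), which
    equalizes the very different curvatures of baseline, stimulus, history
    and coupling terms; ``adaptive=False`` uses the plain constant step.
    """

    def __init__(
        self,
        n: int,
        window: int = 100,
        step: float = 1e-5,
        adaptive: bool = True,
        base_step: float = 0.01,
    ):
        self.params = lnp_init(n, step=step)
        self.window = LNPWindow(n, window=window)
        self.adaptive = adaptive
        self.base_step = base_step
        self._acc: dict[str, np.ndarray] | None = None
        self.loglik: list[float] = []

    def update(self, spikes: np.ndarray, stim: np.ndarray) -> float | None:
        """Push one frame; returns the post-step window log-likelihood once
        the window holds enough frames."""
        self.window.push(spikes, stim)
        if len(self.window) < 10:
            return None
        if not self.adaptive:
            lnp_sgd_step(self.params, self.window)
        else:
            g = lnp_gradient(self.params, self.window)
            if self._acc is None:
                self._acc = {k: np.zeros_like(getattr(g, k)) for k in "bKHW"}
            for name in "bKHW":
                gv = getattr(g, name)
                self._acc[name] += gv * gv
                getattr(self.params, name).__iadd__(
                    self.base_step * gv / np.sqrt(self._acc[name] + 1e-8)
                )
            np.fill_diagonal(self.params.W, 0.0)
        ll = lnp_loglik(self.params, self.window)
        self.loglik.append(ll)
        return ll


def _pack(p: LNPParams) -> np.ndarray:
    return np.concatenate([p.b, p.K.ravel(), p.H.ravel(), p.W.ravel()])


def _unpack(theta: np.ndarray, n: int) -> LNPParams:
    i = 0
    b = theta[i : i + n]; i += n
    K = theta[i : i + n * N_STIM].reshape(n, N_STIM); i += n * N_STIM
    H = theta[i : i + n * N_LAGS].reshape(n, N_LAGS); i += n * N_LAGS
    W = theta[i:].reshape(n, n).copy()
    np.fill_diagonal(W, 0.0)
    return LNPParams(b=b.copy(), K=K.copy(), H=H.copy(), W=W)


def lnp_fit_offline(
    spikes: np.ndarray, stim: np.ndarray, maxiter: int = 500
) -> tuple[LNPParams, float]:
    """Full-data maximum-likelihood reference fit (L-BFGS on the same
    Poisson objective).  Used to benchmark the online fit's convergence."""
    spikes = np.asarray(spikes, dtype=float)
    stim = np.asarray(stim, dtype=float)
    T, n = spikes.shape
    S, X = spikes, stim

    def objective(theta):
        p = _unpack(theta, n)
        eta = np.minimum(_full_drives(p, S, X), _CLIP)
        ll = float(np.sum(S * eta - np.exp(eta)))
        g = _full_gradient(p, S, X, eta)
        return -ll, -_pack(g)

    theta0 = _pack(lnp_init(n))
    res = optimize.minimize(
        objective, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter},
    )
    return _unpack(res.x, n), float(-res.fun)


def _full_drives(p: LNPParams, S: np.ndarray, X: np.ndarray) -> np.ndarray:
    T, n = S.shape
    eta = np.tile(p.b, (T, 1)) + X @ p.K.T
    for lag in range(1, N_LAGS + 1):
        eta[lag:] += p.H[:, lag - 1] * S[:-lag]
    eta[1:] += S[:-1] @ p.W.T
    return eta


def _full_gradient(p: LNPParams, S, X, eta) -> LNPParams:
    R = S - np.exp(eta)
    db = R.sum(axis=0)
    dK = R.T @ X
    dH = np.zeros_like(p.H)
    for lag in range(1, N_LAGS + 1):
        dH[:, lag - 1] = np.sum(R[lag:] * S[:-lag], axis=0)
    dW = R[1:].T @ S[:-1]
    np.fill_diagonal(dW, 0.0)
    return LNPParams(b=db, K=dK, H=dH, W=dW)


def top_connections(W: np.ndarray, i: int, m: int = 10, log=None) -> list[int]:
    """Indices of neuron i's m strongest coupling partners, by |W_ij|
    descending (ties broken toward the lower index); excludes i itself."""
    W = np.asarray(W)
    n = W.shape[1]
    if not (0 <= i < W.shape[0]):
        raise IndexError(f"neuron index {i} out of range")
    others = [j for j in range(n) if j != i]
    if m > n - 1:
        if log is not None:
            log("top-connections", f"m={m} > {n - 1}; returning all")
        m = n - 1
    order = sorted(others, key=lambda j: (-abs(W[i, j]), j))
    return order[:m]
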