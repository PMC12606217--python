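"""Streaming Gaussian-mixture hidden-Markov tiling for trajectory prediction.

The model covers a low-dimensional state space with ``N`` Gaussian tiles
("bubbles") and learns a row-stochastic transition matrix ``A`` between
them, all online:

* one-step prediction — before ingesting a point, the model scores it under
  the predictive mixture ``sum_j (alpha^T A)_j N(x; mu_j, Sigma_j)``;
* filtering — the tile-occupancy vector ``alpha`` follows the standard HMM
  filter (predict with ``A``, reweight by tile likelihoods, renormalize);
* tile adaptation — tile means/covariances are updated from
  responsibility-weighted sufficient statistics with exponential forgetting
  (rate ``lam``) and a prior of strength ``nu`` at the data scale;
* transition learning — ``A`` takes one EM-style convex step of size
  ``eta * alpha_i`` toward the posterior transition responsibilities, which
  keeps rows exactly stochastic while increasing predictive likelihood;
* teleportation — tiles whose recent responsibility mass dies out are
  relocated onto the latest observation with an inflated covariance.

k-step-ahead prediction propagates the filtered state through ``A^k``; the
mixture components stay the current tiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "BubblewrapState",
    "PredictionMetrics",
    "bw_init",
    "bw_update",
    "bw_predict",
    "bw_logpred",
    "bw_entropy",
    "run_bubblewrap",
]

_TELEPORT_WINDOW = 500  # steps over which responsibility mass is averaged
_TELEPORT_THRESHOLD = 1e-4
_COV_FLOOR_FRAC = 1e-6  # eigenvalue floor as a fraction of data variance


@dataclass
class BubblewrapState:
    mu: np.ndarray  # (N, k) tile means
    Sigma: np.ndarray  # (N, k, k) tile covariances (PD)
    A: np.ndarray  # (N, N) row-stochastic transitions
    alpha: np.ndarray  # (N,) filtered tile occupancy (simplex)
    lam: float
    nu: float
    eta: float
    N: int
    k: int
    # sufficient statistics with forgetting
    n_w: np.ndarray = None  # (N,) weighted counts
    m_w: np.ndarray = None  # (N, k) weighted first moments
    S_w: np.ndarray = None  # (N, k, k) weighted second moments
    Sigma0: np.ndarray = None  # (k, k) data-scale prior covariance
    occupancy: np.ndarray = None  # (N,) cumulative responsibilities
    recent_mass: np.ndarray = None  # (N,) EWMA responsibility (teleportation)
    steps: int = 0
    _chol: np.ndarray = None  # (N, k, k) cached Cholesky factors
    _logdet: np.ndarray = None  # (N,)

    def refresh_tile(self, j: int) -> None:
        L = np.linalg.cholesky(self.Sigma[j])
        self._chol[j] = L
        self._logdet[j] = 2.0 * np.sum(np.log(np.diag(L)))

    def log_tile_likelihoods(self, x: np.ndarray) -> np.ndarray:
        """log N(x; mu_j, Sigma_j) for every tile."""
        diffs = x[None, :] - self.mu  # (N, k)
        # solve L z = diff per tile
        z = np.linalg.solve(self._chol, diffs[:, :, None])[:, :, 0]
        maha = np.sum(z * z, axis=1)
        return -0.5 * (self.k * np.log(2 * np.pi) + self._logdet + maha)


def _floor_cov(S: np.ndarray, floor: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (S + S.T))
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def bw_init(
    first_points: np.ndarray,
    N: int = 50,
    lam: float = 1e-3,
    nu: float = 1e-3,
    eta: float = 8e-3,
    seed: int | None = 0,
) -> BubblewrapState:
    """Seed tiles from the first points (typically 20) of projected data."""
    pts = np.atleast_2d(np.asarray(first_points, dtype=float))
    P, k = pts.shape
    if P < 2:
        raise ValueError("need at least 2 points to initialize")
    rng = np.random.default_rng(seed)
    scale = pts.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    mu = np.empty((N, k))
    for j in range(N):
        base = pts[j % P]
        jitter = 0.0 if j < P else 0.1 * scale * rng.standard_normal(k)
        mu[j] = base + jitter
    Sigma0 = np.cov(pts.T, ddof=1).reshape(k, k)
    floor = _COV_FLOOR_FRAC * max(np.trace(Sigma0) / k, 1e-12)
    Sigma0 = _floor_cov(Sigma0 + 1e-6 * np.eye(k), floor)
    state = BubblewrapState(
        mu=mu,
        Sigma=np.repeat(Sigma0[None], N, axis=0),
        A=np.full((N, N), 1.0 / N),
        alpha=np.full(N, 1.0 / N),
        lam=lam, nu=nu, eta=eta, N=N, k=k,
        n_w=np.full(N, nu),
        m_w=nu * mu.copy(),
        S_w=nu * (Sigma0[None] + mu[:, :, None] * mu[:, None, :]),
        Sigma0=Sigma0,
        occupancy=np.zeros(N),
        recent_mass=np.full(N, 1.0 / N),
        _chol=np.zeros((N, k, k)),
        _logdet=np.zeros(N),
    )
    for j in range(N):
        state.refresh_tile(j)
    return state


def bw_update(
    state: BubblewrapState, x: np.ndarray, log=None
) -> tuple[BubblewrapState, float]:
    """Ingest one point; returns (state, one-step log predictive probability).

    The returned log density is evaluated *before* any model update — it is
    an honest prediction of the incoming point.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        if log is not None:
            log("bw-skip", "non-finite observation skipped")
        return state, np.nan
    if x.shape[0] != state.k:
        raise ValueError("dimension mismatch")

    loglik = state.log_tile_likelihoods(x)
    w = state.alpha @ state.A  # predictive tile weights
    logw = np.log(np.maximum(w, 1e-300))
    logp = float(logsumexp(logw + loglik))

    # --- HMM filter / responsibilities
    log_post = logw + loglik
    log_post -= logsumexp(log_post)
    r = np.exp(log_post)
    alpha_prev = state.alpha
    state.alpha = r

    # --- transition EM step (rows stay exactly stochastic)
    with np.errstate(under="ignore"):
        lik_scaled = np.exp(loglik - loglik.max())
    xi = state.A * lik_scaled[None, :]
    row_sums = xi.sum(axis=1, keepdims=True)
    ok = row_sums[:, 0] > 0
    xi[ok] /= row_sums[ok]
    step_i = state.eta * alpha_prev
    state.A[ok] = (1 - step_i[ok, None]) * state.A[ok] + step_i[ok, None] * xi[ok]

    # --- tile sufficient statistics with forgetting
    decay = 1.0 - state.lam
    state.n_w = decay * state.n_w + r
    state.m_w = decay * state.m_w + r[:, None] * x
    state.S_w = decay * state.S_w + r[:, None, None] * np.outer(x, x)
    floor = _COV_FLOOR_FRAC * max(np.trace(state.Sigma0) / state.k, 1e-12)
    touched = np.nonzero(r > 1e-8)[0]
    for j in touched:
        mu_j = state.m_w[j] / state.n_w[j]
        S_emp = state.S_w[j] / state.n_w[j] - np.outer(mu_j, mu_j)
        n_eff = state.n_w[j]
        S_j = (n_eff * S_emp + state.nu * state.Sigma0) / (n_eff + state.nu)
        state.mu[j] = mu_j
        state.Sigma[j] = _floor_cov(S_j, floor)
        state.refresh_tile(j)

    # --- bookkeeping & dead-tile teleportation
    state.occupancy += r
    ew = 1.0 / _TELEPORT_WINDOW
    state.recent_mass = (1 - ew) * state.recent_mass + ew * r
    state.steps += 1
    if state.steps > _TELEPORT_WINDOW:
        j = int(np.argmin(state.recent_mass))
        if state.recent_mass[j] < _TELEPORT_THRESHOLD:
            state.mu[j] = x
            state.Sigma[j] = _floor_cov(2.0 * state.Sigma0, floor)
            state.n_w[j] = state.nu
            state.m_w[j] = state.nu * x
            state.S_w[j] = state.nu * (state.Sigma[j] + np.outer(x, x))
            state.recent_mass[j] = 1.0 / state.N
            state.refresh_tile(j)
            if log is not None:
                log("bw-teleport", f"tile {j} relocated to latest observation")
    return state, logp


def bw_predict(state: BubblewrapState, horizon: int = 1) -> np.ndarray:
    """Tile weights of the horizon-k predictive mixture: alpha^T A^k."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    Ak = np.linalg.matrix_power(state.A, horizon)
    return state.alpha @ Ak


def bw_logpred(state: BubblewrapState, x_future: np.ndarray, horizon: int = 1) -> float:
    """Log density of the horizon-k predictive mixture at ``x_future``."""
    w = bw_predict(state, horizon)
    loglik = state.log_tile_likelihoods(np.asarray(x_future, dtype=float).ravel())
    return float(logsumexp(np.log(np.maximum(w, 1e-300)) + loglik))


def bw_entropy(state: BubblewrapState) -> float:
    """Occupancy-weighted mean row entropy of A, in bits."""
    tot = state.occupancy.sum()
    pi = state.occupancy / tot if tot > 0 else np.full(state.N, 1.0 / state.N)
    A = state.A
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(A > 0, A * np.log2(A), 0.0)
    row_h = -terms.sum(axis=1)
    return float(pi @ row_h)


@dataclass
class PredictionMetrics:
    """Per-step predictive metrics with exponentially weighted averages."""

    log_pred_prob: list = field(default_factory=list)
    entropy: list = field(default_factory=list)
    ewma_logp: list = field(default_factory=list)
    ewma_entropy: list = field(default_factory=list)
    decay: float = 0.99

    def append(self, logp: float, entropy: float) -> None:
        self.log_pred_prob.append(logp)
        self.entropy.append(entropy)
        prev_l = self.ewma_logp[-1] if self.ewma_logp else logp
        prev_h = self.ewma_entropy[-1] if self.ewma_entropy else entropy
        self.ewma_logp.append(self.decay * prev_l + (1 - self.decay) * logp)
        self.ewma_entropy.append(self.decay * prev_h + (1 - self.decay) * entropy)


def run_bubblewrap(
    data: np.ndarray,
    N: int = 50,
    n_init: int = 20,
    lam: float = 1e-3,
    nu: float = 1e-3,
    eta: float = 8e-3,
    horizons: tuple[int, ...] = (),
    seed: int = 0,
) -> tuple[BubblewrapState, PredictionMetrics, dict[int, list[float]]]:
    """Stream a (T, k) array through the model.

    Returns the final state, per-step one-step metrics, and — for each
    requested horizon h — the log predictive probabilities of ``x[t+h]``
    under the filtered state at time t.
    """
    data = np.asarray(data, dtype=float)
    T = data.shape[0]
    state = bw_init(data[:n_init], N=N, lam=lam, nu=nu, eta=eta, seed=seed)
    metrics = PredictionMetrics()
    horizon_logp: dict[int, list[float]] = {h: [] for h in horizons}
    for t in range(n_init, T):
        for h in horizons:
            if t + h - 1 < T:
                # predict x[t+h-1] before seeing x[t] (state is at t-1)
                horizon_logp[h].append(bw_logpred(state, data[t + h - 1], h))
        state, logp = bw_update(state, data[t])
        metrics.append(logp, bw_entropy(state))
    return state, metrics, horizon_logp
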