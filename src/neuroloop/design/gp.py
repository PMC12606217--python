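"""Gaussian-process tuning-surface estimation on a toroidal stimulus grid.

The stimulus space is a 24 x 24 grid of binocular motion directions — one
angle per eye, in 15-degree steps — with circular boundary conditions on
both axes (359 deg is next to 0 deg).  The GP uses a squared-exponential
kernel on the toroidal distance, grid coordinates normalized to [0, 1), so
a length scale of ``c/24`` corresponds to ``c`` grid steps.

The posterior over all 576 grid points is exact GP regression; repeated
observations at one grid point are handled natively by collapsing them to
their mean with observation-noise variance ``sigma_n^2 / n`` — algebraically
identical to including every repeat in the dense system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["GRID", "N_POINTS", "GPKernel", "GPPosterior", "gp_fit",
           "grid_kernel_matrix", "toroidal_sqdist", "angle_to_index",
           "index_to_angle"]

GRID = 24
N_POINTS = GRID * GRID
ANGLE_STEP = 15.0


def angle_to_index(angle_left: float, angle_right: float) -> int:
    """Linear grid index of an (angle_left, angle_right) stimulus pair."""
    i = int(round(angle_left / ANGLE_STEP)) % GRID
    j = int(round(angle_right / ANGLE_STEP)) % GRID
    return i * GRID + j


def index_to_angle(p: int) -> tuple[float, float]:
    return (p // GRID) * ANGLE_STEP, (p % GRID) * ANGLE_STEP


@dataclass(frozen=True)
class GPKernel:
    length_scale: float = 3.0 / GRID  # three grid steps, in normalized units
    signal_var: float = 1.0
    noise_var: float = 1e-2


def toroidal_sqdist() -> np.ndarray:
    """(576, 576) squared toroidal distance in normalized grid coordinates."""
    idx = np.arange(N_POINTS)
    xi, yi = idx // GRID, idx % GRID
    dx = np.abs(xi[:, None] - xi[None, :])
    dy = np.abs(yi[:, None] - yi[None, :])
    dx = np.minimum(dx, GRID - dx) / GRID
    dy = np.minimum(dy, GRID - dy) / GRID
    return dx.astype(float) ** 2 + dy.astype(float) ** 2


_SQDIST: np.ndarray | None = None
_KCACHE: dict[float, np.ndarray] = {}


def grid_kernel_matrix(kernel: GPKernel) -> np.ndarray:
    """Full kernel matrix over the grid.

    The unit-signal correlation matrix is cached per length scale (the
    signal variance is a cheap scalar multiple)."""
    global _SQDIST
    K = _KCACHE.get(kernel.length_scale)
    if K is None:
        if _SQDIST is None:
            _SQDIST = toroidal_sqdist()
        K = np.exp(-0.5 * _SQDIST / kernel.length_scale**2)
        if len(_KCACHE) > 8:
            _KCACHE.clear()
        _KCACHE[kernel.length_scale] = K
    return kernel.signal_var * K


@dataclass
class GPPosterior:
    f: np.ndarray  # (24, 24) posterior mean
    sigma: np.ndarray  # (24, 24) posterior sd
    observations: list  # [(grid index, response), ...]
    kernel: GPKernel

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.f))


def gp_fit(observations: list[tuple[int, float]], kernel: GPKernel) -> GPPosterior:
    """Exact GP posterior mean and sd over all 576 grid points."""
    prior_sd = np.full(N_POINTS, np.sqrt(kernel.signal_var))
    if len(observations) == 0:
        return GPPosterior(
            f=np.zeros((GRID, GRID)), sigma=prior_sd.reshape(GRID, GRID),
            observations=[], kernel=kernel,
        )
    pts: dict[int, list[float]] = {}
    for p, y in observations:
        pts.setdefault(int(p), []).append(float(y))
    idx = np.array(sorted(pts))
    counts = np.array([len(pts[p]) for p in idx], dtype=float)
    if kernel.noise_var == 0 and np.any(counts > 1):
        raise np.linalg.LinAlgError(
            "singular GP system: zero observation noise with repeated "
            "points; set a positive noise floor"
        )
    ymean = np.array([np.mean(pts[p]) for p in idx])

    K = grid_kernel_matrix(kernel)
    Kxx = K[np.ix_(idx, idx)] + np.diag(kernel.noise_var / counts)
    try:
        cf = linalg.cho_factor(Kxx)
    except linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular GP system (zero observation noise with repeated "
            "points?); set a positive noise floor"
        )
    Ks = K[:, idx]  # (576, m)
    f = Ks @ linalg.cho_solve(cf, ymean)
    var = np.diag(K) - np.sum(Ks * linalg.cho_solve(cf, Ks.T).T, axis=1)
    sigma = np.sqrt(np.clip(var, 0.0, None))
    return GPPosterior(
        f=f.reshape(GRID, GRID), sigma=sigma.reshape(GRID, GRID),
        observations=list(observations), kernel=kernel,
    )
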