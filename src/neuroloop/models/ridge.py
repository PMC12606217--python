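"""Streaming ridge regression via running sufficient statistics.

Each datum is seen exactly once: the k x k feature Gram matrix and the
k x n cross-moment are accumulated, and the coefficients solving
``(X^T X + lambda I) beta = X^T Y`` are available after every sample —
identical (to solver precision) to the batch ridge fit on the same prefix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["RidgeState", "ridge_init", "ridge_update", "ridge_coefficients",
           "project_coefficients_to_pixels"]


@dataclass
class RidgeState:
    G: np.ndarray  # k x k running Gram (without the ridge term)
    C: np.ndarray  # k x n running cross-moment
    lam: float
    n_obs: int

    @property
    def P(self) -> np.ndarray:
        """Regularized accumulator G + lambda*I (symmetric PD for lam > 0)."""
        return self.G + self.lam * np.eye(self.G.shape[0])


def ridge_init(k: int, n_targets: int, lam: float = 1e-5) -> RidgeState:
    return RidgeState(G=np.zeros((k, k)), C=np.zeros((k, n_targets)), lam=lam, n_obs=0)


def ridge_update(state: RidgeState, x: np.ndarray, y: np.ndarray) -> RidgeState:
    """Fold one (feature, target) pair into the sufficient statistics."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input")
    if x.shape[0] != state.G.shape[0] or y.shape[0] != state.C.shape[1]:
        raise ValueError("dimension mismatch")
    state.G += np.outer(x, x)
    state.C += np.outer(x, y)
    state.n_obs += 1
    return state


def ridge_coefficients(state: RidgeState) -> np.ndarray:
    """Solve (G + lambda I) beta = C; beta is k x n_targets."""
    return linalg.solve(state.P, state.C, assume_a="pos")


def project_coefficients_to_pixels(
    beta: np.ndarray, Q: np.ndarray, image_shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Map regression coefficients back to pixel space: Q @ beta, normalized
    to the top coefficient (max absolute entry scaled to 1)."""
    weight = np.asarray(Q) @ np.asarray(beta)
    peak = np.abs(weight).max()
    if peak > 0:
        weight = weight / peak
    if image_shape is not None:
        weight = weight.reshape(image_shape + weight.shape[1:])
    return weight
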