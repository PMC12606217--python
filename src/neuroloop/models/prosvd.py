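"""Streaming SVD subspace tracking with procrustean basis stabilization.

Tracks the top-k left singular subspace of a growing data matrix one column
at a time.  After each rank-one extension the updated basis is rotated back
onto the previous one by an orthogonal Procrustes alignment, so basis
vectors move as little as the subspace change allows — downstream consumers
(regressors, tiling models) see stable coordinates instead of the arbitrary
rotations a plain incremental SVD would produce.

State: ``Q`` (d x k, orthonormal columns) and ``B`` (k x k), where ``B``
carries the singular-value structure of the data seen so far (right
singular rotations are dropped; they do not affect the left subspace).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["ProSVDState", "prosvd_init", "prosvd_update", "project"]

_EPS_PERP = 1e-10


@dataclass
class ProSVDState:
    Q: np.ndarray  # d x k orthonormal basis
    B: np.ndarray  # k x k singular-structure carrier
    k: int
    seen: int  # columns processed (including the init block)


def prosvd_init(first_block: np.ndarray, k: int) -> ProSVDState:
    """Initialize from the first l >= k columns of data."""
    A = np.asarray(first_block, dtype=float)
    if A.ndim != 2:
        raise ValueError("first_block must be a d x l matrix")
    d, l = A.shape
    if l < k:
        raise ValueError(f"need at least k={k} columns to initialize, got {l}")
    U, s, _ = linalg.svd(A, full_matrices=False)
    if k > 0 and (len(s) < k or s[k - 1] <= max(d, l) * np.finfo(float).eps * (s[0] if len(s) else 0) or s[k - 1] == 0):
        raise ValueError(f"initial block has rank < k={k}")
    return ProSVDState(Q=U[:, :k].copy(), B=np.diag(s[:k]), k=k, seen=l)


def prosvd_update(state: ProSVDState, x: np.ndarray) -> ProSVDState:
    """Fold one new column into the tracked subspace.

    The new basis spans the top-k left subspace of ``[data so far, x]`` and
    is Procrustes-aligned to the previous ``Q`` (minimal rotation).
    """
    x = np.asarray(x, dtype=float).ravel()
    d = state.Q.shape[0]
    if x.shape[0] != d:
        raise ValueError(f"dimension mismatch: expected {d}, got {x.shape[0]}")
    k = state.k
    proj = state.Q.T @ x
    resid = x - state.Q @ proj
    rho = float(np.linalg.norm(resid))

    if rho > _EPS_PERP * max(1.0, float(np.linalg.norm(x))):
        u_perp = resid / rho
        Q_ext = np.column_stack([state.Q, u_perp])
        B_aug = np.zeros((k + 1, k + 1))
        B_aug[:k, :k] = state.B
        B_aug[:k, k] = proj
        B_aug[k, k] = rho
    else:
        Q_ext = state.Q
        B_aug = np.column_stack([state.B, proj])

    U1, s1, _ = linalg.svd(B_aug, full_matrices=False)
    U1k = U1[:, :k]
    # orthogonal Procrustes: rotate the candidate basis onto the previous one
    M = U1k[:k, :].T  # = (Q_ext @ U1k)^T @ Q_old
    Up, _, Vpt = linalg.svd(M)
    T = Up @ Vpt
    Q_new = Q_ext @ (U1k @ T)
    B_new = T.T @ np.diag(s1[:k])
    return ProSVDState(Q=Q_new, B=B_new, k=k, seen=state.seen + 1)


def project(state: ProSVDState, x: np.ndarray) -> np.ndarray:
    """Coordinates of ``x`` in the current basis (Q^T x)."""
    return state.Q.T @ np.asarray(x, dtype=float)
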