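"""Patient similarity network construction by similarity network fusion.

Per view, pairwise Euclidean distances become a scaled exponential kernel
affinity W; W is normalized two ways — a full transition matrix P (rows sum
to 1, half the mass on the diagonal) and a local matrix S restricted to each
patient's K nearest neighbors. Fusion then iterates the cross-diffusion
update

    P^(h)  <-  S^(h) · mean_{k != h} P^(k) · S^(h)^T

re-normalizing after every round, and finally averages the per-view matrices
and symmetrizes. The fused matrix serves as a weighted adjacency for the
graph classifier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

EPS = 1e-12


@dataclass
class AffinityMatrix:
    """An n x n nonnegative patient-patient similarity matrix.

    ``kind`` records the construction: "W" (raw kernel), "P" (full
    normalization, row-stochastic) or "S" (local, row-stochastic over the
    K-neighborhood and zero elsewhere).
    """

    values: np.ndarray
    sample_ids: list[str] | None = None
    kind: str = "W"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("affinity matrix must be square")
        if self.sample_ids is not None and len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")


@dataclass
class FusedNetwork:
    """The fused patient similarity network (symmetric, nonnegative)."""

    values: np.ndarray
    sample_ids: list[str] | None = None
    m: int = 0
    iterations: int = 0


def _as_array(x) -> np.ndarray:
    return x.values if isinstance(x, (AffinityMatrix, FusedNetwork)) else np.asarray(x, dtype=float)


def default_k(n: int) -> int:
    """Default neighborhood size: max(3, round(n/10)), capped at n-1."""
    return min(max(3, round(n / 10)), n - 1)


def pairwise_distance(X: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix between sample rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two samples")
    D = cdist(X, X, metric="euclidean")
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def _knn_mean_distance(D: np.ndarray, K: int) -> np.ndarray:
    """Mean distance from each sample to its K nearest neighbors (self excluded).

    Ties are broken toward the smaller sample index (stable sort) so results
    are deterministic.
    """
    n = D.shape[0]
    masked = D.copy()
    np.fill_diagonal(masked, np.inf)
    order = np.argsort(masked, axis=1, kind="stable")
    idx = order[:, :K]
    return masked[np.arange(n)[:, None], idx].mean(axis=1)


def affinity_matrix(
    D: np.ndarray,
    K: int,
    alpha: float = 0.5,
    sample_ids: list[str] | None = None,
) -> AffinityMatrix:
    """Scaled exponential kernel affinity W from a distance matrix.

    W_ij = exp(-d_ij^2 / (alpha * gamma_ij)) with the scaling term
    gamma_ij = (mean K-NN distance of i + mean K-NN distance of j + d_ij) / 3,
    which adapts the kernel bandwidth to local density. Entries lie in (0, 1];
    the diagonal is exactly 1.
    """
    D = _as_array(D)
    n = D.shape[0]
    if not 1 <= K <= n - 1:
        raise ValueError(f"K must be in [1, {n - 1}], got {K}")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    mu = _knn_mean_distance(D, K)
    gamma = (mu[:, None] + mu[None, :] + D) / 3.0
    degenerate = gamma <= 0
    if degenerate.any():
        warnings.warn(
            "degenerate zero scaling term clamped to eps (duplicate points?)",
            stacklevel=2,
        )
        gamma = np.where(degenerate, EPS, gamma)
    W = np.exp(-(D**2) / (alpha * gamma))
    return AffinityMatrix(W, sample_ids=sample_ids, kind="W")


def normalize_full(W) -> AffinityMatrix:
    """Full normalization P: off-diagonal mass halved row-wise, diagonal 1/2.

    P_ij = W_ij / (2 * sum_{k != i} W_ik) for j != i and P_ii = 1/2, so every
    row sums exactly to 1.
    """
    A = _as_array(W)
    sample_ids = getattr(W, "sample_ids", None)
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    if (row <= 0).any():
        raise ValueError("row with zero off-diagonal affinity; cannot normalize")
    P = off / (2.0 * row[:, None])
    np.fill_diagonal(P, 0.5)
    return AffinityMatrix(P, sample_ids=sample_ids, kind="P")


def _neighborhoods(W: np.ndarray, K: int) -> np.ndarray:
    """Indices of the K most similar neighbors per row, self excluded.

    Ties broken toward the smaller index for determinism.
    """
    n = W.shape[0]
    masked = W.copy()
    np.fill_diagonal(masked, -np.inf)
    order = np.argsort(-masked, axis=1, kind="stable")
    return order[:, :K]


def local_affinity(W, K: int) -> AffinityMatrix:
    """Local affinity S: row-normalized W restricted to K nearest neighbors.

    S_ij = W_ij / sum_{k in N_i} W_ik for j in N_i, 0 otherwise, where N_i is
    the set of i's K most similar patients (excluding i). Rows sum to 1 over
    the neighborhood.
    """
    A = _as_array(W)
    sample_ids = getattr(W, "sample_ids", None)
    n = A.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    K = min(K, n - 1)
    nbrs = _neighborhoods(A, K)
    S = np.zeros_like(A)
    rows = np.repeat(np.arange(n), K)
    cols = nbrs.ravel()
    S[rows, cols] = A[rows, cols]
    denom = S.sum(axis=1)
    if (denom <= 0).any():
        raise ValueError("zero total affinity over a neighborhood")
    S /= denom[:, None]
    return AffinityMatrix(S, sample_ids=sample_ids, kind="S")


def snf_fuse(
    Ws: Sequence[AffinityMatrix | np.ndarray],
    K: int,
    T: int = 20,
    return_trace: bool = False,
) -> FusedNetwork | tuple[FusedNetwork, list[list[np.ndarray]]]:
    """Fuse m >= 2 per-view affinities by iterative cross-diffusion.

    Each view's P is updated through its own local structure S against the
    average of the other views' P matrices, re-normalized after every round;
    after T rounds the views are averaged and symmetrized. With
    ``return_trace`` the per-round re-normalized P matrices are also
    returned (for diagnostics and invariant checks).
    """
    m = len(Ws)
    if m < 2:
        raise ValueError("fusion needs at least two views (m-1 appears in the update)")
    arrays = [_as_array(W) for W in Ws]
    n = arrays[0].shape[0]
    ids = [getattr(W, "sample_ids", None) for W in Ws]
    ref_ids = next((i for i in ids if i is not None), None)
    for a, i in zip(arrays, ids):
        if a.shape != (n, n):
            raise ValueError("all views must share the same size")
        if ref_ids is not None and i is not None and i != ref_ids:
            raise ValueError("mismatched sample orders across views")
    if T < 0:
        raise ValueError("T must be >= 0")

    Ps = [normalize_full(a).values for a in arrays]
    Ss = [local_affinity(a, K).values for a in arrays]
    trace: list[list[np.ndarray]] = []
    for _ in range(T):
        new = []
        for h in range(m):
            others = sum(Ps[k] for k in range(m) if k != h) / (m - 1)
            new.append(Ss[h] @ others @ Ss[h].T)
        Ps = [normalize_full(p).values for p in new]
        if return_trace:
            trace.append([p.copy() for p in Ps])
    fused = sum(Ps) / m
    fused = (fused + fused.T) / 2.0
    logger.info("fused %d views over %d iterations (n=%d)", m, T, n)
    result = FusedNetwork(fused, sample_ids=ref_ids, m=m, iterations=T)
    return (result, trace) if return_trace else result
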