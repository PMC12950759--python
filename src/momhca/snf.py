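"""Similarity network fusion (SNF) over the two modality representations.

Per modality v the cell affinity is a locally scaled Gaussian kernel on
Euclidean distances,

    W(i,j) = exp(−ρ(i,j)² / (μ · ε_ij)),

with ε_ij the standard SNF local scale: (mean distance of i to its K
nearest neighbours + same for j + ρ(i,j)) / 3. Two kernels are derived:
the full transition kernel P (diagonal 1/2, off-diagonal half-stochastic)
and the sparse kNN kernel S (row-stochastic on the K nearest neighbours).
Cross-diffusion then iterates

    P₁ ← S₁ · P₂ · S₁ᵀ,   P₂ ← S₂ · P₁ · S₂ᵀ   (simultaneous updates),

renormalising each iterate back to the P structure, and the fused matrix
is the symmetrised average (P₁ + P₂)/2, which doubles as the GCN adjacency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

__all__ = [
    "SNFConfig",
    "SimilarityBundle",
    "pairwise_distance",
    "affinity",
    "full_kernel",
    "knn_kernel",
    "snf_fuse",
    "build_adjacency",
    "snf_pipeline",
]


@dataclass
class SNFConfig:
    n_neighbors: int = 9
    mu: float = 0.5
    iterations: int = 20
    distance: str = "squared_euclidean"
    renormalize: bool = True
    convergence_tol: float = 1e-6

    def __post_init__(self):
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.distance not in ("euclidean", "squared_euclidean"):
            raise ValueError(f"unknown distance {self.distance!r}")


@dataclass
class SimilarityBundle:
    """Per-modality affinity (W), full kernel (P), sparse kNN kernel (S)
    and the fused similarity matrix."""

    W: list[np.ndarray] = field(default_factory=list)
    P: list[np.ndarray] = field(default_factory=list)
    S: list[np.ndarray] = field(default_factory=list)
    fused: np.ndarray | None = None


def pairwise_distance(X: np.ndarray, squared: bool = False) -> np.ndarray:
    """Symmetric Euclidean (optionally squared) distance matrix with zero
    diagonal."""
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in feature matrix")
    D = cdist(X, X, metric="sqeuclidean" if squared else "euclidean")
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


def _mean_knn_dist(dist: np.ndarray, K: int) -> np.ndarray:
    """Mean distance of each point to its K nearest neighbours (self
    excluded; ties broken by smaller index via stable sort)."""
    n = dist.shape[0]
    if K >= n:
        raise ValueError(f"K={K} must be < N={n}")
    means = np.empty(n)
    for i in range(n):
        d = np.delete(dist[i], i)
        means[i] = np.sort(d, kind="stable")[:K].mean()
    return means


def affinity(dist: np.ndarray, cfg: SNFConfig | None = None) -> np.ndarray:
    """Locally scaled Gaussian affinity W(i,j) = exp(−ρ²/(μ ε_ij)),
    ε_ij = (mean K-NN distance of i + of j + ρ(i,j)) / 3."""
    cfg = cfg or SNFConfig()
    dist = np.asarray(dist, dtype=np.float64)
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    mk = _mean_knn_dist(dist, cfg.n_neighbors)
    eps = (mk[:, None] + mk[None, :] + dist) / 3.0
    floor = np.finfo(np.float64).eps
    if np.any(eps <= 0):
        warnings.warn("coincident points: local scale floored at machine epsilon")
        eps = np.maximum(eps, floor)
    W = np.exp(-(dist ** 2) / (cfg.mu * eps))
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 1.0)
    return W


def full_kernel(W: np.ndarray) -> np.ndarray:
    """P(i,j) = W(i,j) / (2 Σ_{k≠i} W(i,k)) off-diagonal, 1/2 on the
    diagonal; every row sums to 1."""
    W = np.asarray(W, dtype=np.float64)
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    if np.any(row <= 0):
        i = int(np.argmax(row <= 0))
        raise ValueError(f"cell {i} is isolated (zero off-diagonal affinity)")
    P = off / (2.0 * row[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def knn_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """S(i,j) = W(i,j)/Σ_{k∈N_i} W(i,k) on the K nearest neighbours of i
    (by affinity, self excluded; ties at the boundary broken by smaller
    index), zero elsewhere. Row-stochastic on its support."""
    W = np.asarray(W, dtype=np.float64)
    n = W.shape[0]
    if K >= n:
        raise ValueError(f"K={K} must be < N={n}")
    S = np.zeros_like(W)
    for i in range(n):
        w = W[i].copy()
        w[i] = -np.inf  # exclude self from the neighbour set
        order = np.lexsort((np.arange(n), -w))  # descending affinity, ties → smaller index
        nbrs = order[:K]
        denom = W[i, nbrs].sum()
        if denom <= 0:
            raise ValueError(f"cell {i} has zero affinity to its {K} nearest neighbours")
        S[i, nbrs] = W[i, nbrs] / denom
    return S


def _renormalize(P: np.ndarray) -> np.ndarray:
    """Restore the full-kernel structure (diagonal 1/2, off-diagonal rows
    summing to 1/2) after a diffusion step."""
    off = P.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    row = np.maximum(row, np.finfo(np.float64).tiny)
    out = off / (2.0 * row[:, None])
    np.fill_diagonal(out, 0.5)
    return out


def snf_fuse(P1: np.ndarray, P2: np.ndarray, S1: np.ndarray, S2: np.ndarray,
             t: int = 20, renormalize: bool = True,
             convergence_tol: float = 1e-6,
             iterate_log: list | None = None) -> np.ndarray:
    """Cross-diffuse the two modality kernels and return the symmetrised
    average of the final iterates. When `iterate_log` is a list, the
    (P1, P2) pair after every update is appended to it."""
    mats = [np.asarray(m, dtype=np.float64) for m in (P1, P2, S1, S2)]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1 or any(m.ndim != 2 or m.shape[0] != m.shape[1] for m in mats):
        raise ValueError("P1, P2, S1, S2 must all be square with identical shapes")
    if t < 1:
        raise ValueError("t must be >= 1")
    P1, P2, S1, S2 = mats
    for _ in range(t):
        P1_new = S1 @ P2 @ S1.T
        P2_new = S2 @ P1 @ S2.T
        if renormalize:
            P1_new = _renormalize(P1_new)
            P2_new = _renormalize(P2_new)
        P1, P2 = P1_new, P2_new
        if iterate_log is not None:
            iterate_log.append((P1.copy(), P2.copy()))
        if convergence_tol > 0:
            denom = np.linalg.norm(P1)
            if denom > 0 and np.linalg.norm(P1 - P2) / denom < convergence_tol:
                break
    fused = 0.5 * (P1 + P2)
    return 0.5 * (fused + fused.T)


def build_adjacency(fused: np.ndarray, self_loops: bool = True,
                    top_k: int | None = None) -> np.ndarray:
    """Adjacency for the GCN: the fused similarity, optionally sparsified
    to the top-K entries per row (re-symmetrised), with self-loops added."""
    A = np.asarray(fused, dtype=np.float64).copy()
    if np.any(A < 0):
        raise ValueError("fused similarity must be nonnegative")
    if top_k is not None:
        n = A.shape[0]
        mask = np.zeros_like(A, dtype=bool)
        off = A.copy()
        np.fill_diagonal(off, -np.inf)
        for i in range(n):
            order = np.lexsort((np.arange(n), -off[i]))
            mask[i, order[:top_k]] = True
        mask |= mask.T
        A = np.where(mask, A, 0.0)
    A = 0.5 * (A + A.T)
    if self_loops:
        A = A + np.eye(A.shape[0])
    return A


def snf_pipeline(X1: np.ndarray, X2: np.ndarray,
                 cfg: SNFConfig | None = None) -> SimilarityBundle:
    """Distance → affinity → kernels → cross-diffusion for two modality
    feature matrices with matched cell order."""
    cfg = cfg or SNFConfig()
    bundle = SimilarityBundle()
    for X in (X1, X2):
        D = pairwise_distance(X, squared=False)
        W = affinity(D, cfg)
        bundle.W.append(W)
        bundle.P.append(full_kernel(W))
        bundle.S.append(knn_kernel(W, cfg.n_neighbors))
    bundle.fused = snf_fuse(bundle.P[0], bundle.P[1], bundle.S[0], bundle.S[1],
                            t=cfg.iterations, renormalize=cfg.renormalize,
                            convergence_tol=cfg.convergence_tol)
    return bundle
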