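"""Similarity network fusion of band-specific brain networks.

High- and low-frequency networks carry complementary connectivity
structure.  Cross-diffusion blends them: each network is iteratively
updated through the other using KNN-sparsified kernels,

    W_high <- S_high . W_low . S_high^T
    W_low  <- S_low  . W_high . S_low^T

until both iterates change by at most ``tol`` in Frobenius norm, and
the two final iterates are averaged into the fused network.  The sparse
kernels S route diffusion through each node's strongest connections,
which suppresses weak/noisy edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import _as_array

__all__ = ["SimilarityKernel", "FusionState", "knn_kernel", "snf_fuse",
           "concatenate_baseline", "DEFAULT_K"]

DEFAULT_K = 11  # nearest-neighbour count of the framework


@dataclass
class SimilarityKernel:
    """KNN-sparsified affinity matrix: column j keeps its k strongest rows."""

    values: np.ndarray
    k: int


@dataclass
class FusionState:
    """Final iterates and convergence information of one fusion run."""

    p_high: np.ndarray
    p_low: np.ndarray
    g: int
    converged: bool
    delta_high: float
    delta_low: float


def knn_kernel(W, k: int) -> SimilarityKernel:
    """KNN-sparsify |W|: S_ij = |W_ij| if i is a k-nearest neighbour of j.

    Neighbourhoods are per column; ties at rank k are all kept, so a
    column may retain more than k entries under ties.  The diagonal is
    zeroed first and never counts as a neighbour.
    """
    A = np.abs(_as_array(W)).copy()
    P = A.shape[0]
    if not 1 <= k <= P - 1:
        raise ValueError(f"k must be in [1, {P - 1}], got {k}")
    np.fill_diagonal(A, 0.0)
    S = np.zeros_like(A)
    for j in range(P):
        col = A[:, j]
        order = np.argsort(col)[::-1]
        cutoff = col[order[k - 1]]
        keep = col >= cutoff if cutoff > 0 else np.zeros(P, bool)
        if cutoff > 0:
            S[keep, j] = col[keep]
        else:  # fewer than k positive affinities: keep what is nonzero
            S[col > 0, j] = col[col > 0]
    return SimilarityKernel(values=S, k=k)


def _row_normalize(M: np.ndarray) -> np.ndarray:
    sums = M.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return M / sums


def _full_kernel(M: np.ndarray) -> np.ndarray:
    """Kernel normalisation with half the mass held on the diagonal.

    Off-diagonal rows are scaled to sum to 1/2 and the diagonal is set
    to 1/2.  Keeping this self-affinity is what stops the diffusion
    from flattening to the uniform matrix: each update re-injects the
    node's own neighbourhood structure through S . S^T.
    """
    B = M.copy()
    np.fill_diagonal(B, 0.0)
    sums = B.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    P = B / (2.0 * sums)
    np.fill_diagonal(P, 0.5)
    return P


def _symmetrize(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def snf_fuse(w_high, w_low, k: int = DEFAULT_K, tol: float = 0.01,
             max_iter: int = 100, mode: str = "normalized",
             return_state: bool = False):
    """Fuse two networks by cross-diffusion through KNN kernels.

    ``mode='normalized'`` row-normalises the sparse kernels S and
    applies the half-diagonal kernel normalisation to the dense
    iterates P every iteration (diag 1/2, off-diagonal rows summing to
    1/2), which keeps scales bounded and preserves each subject's own
    structure; ``mode='literal'`` iterates the raw products
    S . P . S^T without any normalisation.  Updates are simultaneous
    (each side diffuses through the other's previous iterate) and
    symmetrised after each product.
    Iteration stops when the Frobenius change of BOTH iterates is at
    most ``tol``; the fused network is the elementwise average of the
    final iterates with a zero diagonal.
    """
    if mode not in ("normalized", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    wh, wl = _as_array(w_high), _as_array(w_low)
    if wh.shape != wl.shape or wh.ndim != 2:
        raise ValueError("both networks must be P x P with equal P")

    s_high = knn_kernel(wh, k).values
    s_low = knn_kernel(wl, k).values
    p_high, p_low = np.abs(wh).copy(), np.abs(wl).copy()
    np.fill_diagonal(p_high, 0.0)
    np.fill_diagonal(p_low, 0.0)
    if mode == "normalized":
        # the diffusion kernel keeps half its mass on the node itself
        # (a node is always its own nearest neighbour); without this
        # self-affinity the products S . P . S^T only mix shared-
        # neighbour terms and direct edge strength is lost
        s_high = 0.5 * _row_normalize(s_high) + 0.5 * np.eye(len(s_high))
        s_low = 0.5 * _row_normalize(s_low) + 0.5 * np.eye(len(s_low))
        p_high = _symmetrize(_full_kernel(p_high))
        p_low = _symmetrize(_full_kernel(p_low))

    converged = False
    dh = dl = np.inf
    g = 0
    for g in range(1, max_iter + 1):
        new_high = _symmetrize(s_high @ p_low @ s_high.T)
        new_low = _symmetrize(s_low @ p_high @ s_low.T)
        if mode == "normalized":
            new_high = _symmetrize(_full_kernel(new_high))
            new_low = _symmetrize(_full_kernel(new_low))
        dh = float(np.linalg.norm(new_high - p_high))
        dl = float(np.linalg.norm(new_low - p_low))
        p_high, p_low = new_high, new_low
        if dh <= tol and dl <= tol:
            converged = True
            break

    fused = 0.5 * (p_high + p_low)
    np.fill_diagonal(fused, 0.0)
    if return_state:
        return fused, FusionState(p_high=p_high, p_low=p_low, g=g,
                                  converged=converged, delta_high=dh,
                                  delta_low=dl)
    return fused


def concatenate_baseline(w_high, w_low) -> np.ndarray:
    """Feature-level baseline: splice both upper triangles into one vector."""
    wh, wl = _as_array(w_high), _as_array(w_low)
    if wh.shape != wl.shape:
        raise ValueError("shape mismatch between band networks")
    iu = np.triu_indices(wh.shape[0], k=1)
    return np.concatenate([wh[iu], wl[iu]])
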