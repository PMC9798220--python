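"""Functional brain network construction from ROI time series.

Two estimators of the P x P connectivity matrix W are provided: full
Pearson correlation (optionally sparsified by keeping the strongest
fraction of edges) and sparse representation, an l1-regularised
regression of each ROI's signal on all the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import Lasso

__all__ = [
    "ConnectivityMatrix",
    "normalize_roi_signals",
    "pearson_network",
    "threshold_network",
    "sparse_representation_network",
    "PearsonConnectivity",
    "SparseConnectivity",
    "LAMBDA_GRID",
    "SPARSITY_GRID",
]

# hyperparameter grids searched by inner cross-validation:
# regularisation weights for sparse representation and kept-edge
# fractions for thresholded Pearson networks
LAMBDA_GRID = [round(0.1 + 0.05 * i, 2) for i in range(19)]  # 0.10 .. 1.00
SPARSITY_GRID = [round(0.05 * i, 2) for i in range(1, 20)] + [0.99]


@dataclass
class ConnectivityMatrix:
    """A symmetric P x P functional network with provenance tags."""

    values: np.ndarray
    kind: str = "pc"          # {pc, sr, fused}
    band: str = "full"        # {high, low, full, fused}
    sparsity_applied: float | None = None

    def __post_init__(self):
        W = np.asarray(self.values, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if np.abs(W - W.T).max() > 1e-9:
            raise ValueError("connectivity matrix must be symmetric")
        self.values = W

    @property
    def P(self) -> int:
        return self.values.shape[0]


def _as_array(W) -> np.ndarray:
    return W.values if isinstance(W, ConnectivityMatrix) else np.asarray(W, float)


def normalize_roi_signals(X: np.ndarray) -> np.ndarray:
    """Standardise each ROI's series: r(x) = (x - mu_i) / sigma_i."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a P x T matrix")
    sd = X.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance signal in ROI(s) {bad.tolist()}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def pearson_network(X: np.ndarray) -> np.ndarray:
    """Pearson correlation network: W_ij = corr(x_i, x_j), diag = 1."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(
            f"zero-variance signal in ROI(s) {np.where(sd == 0)[0].tolist()}")
    C = X - X.mean(axis=1, keepdims=True)
    W = C @ C.T
    norms = np.sqrt(np.diag(W))
    W /= np.outer(norms, norms)
    np.fill_diagonal(W, 1.0)
    return 0.5 * (W + W.T)  # remove last-bit asymmetry


def threshold_network(W, keep_fraction: float) -> np.ndarray:
    """Keep the ``keep_fraction`` of edges with largest |W_ij|.

    The cutoff is the magnitude of the ceil(keep_fraction * E)-th largest
    upper-triangle entry; ties at the cutoff are all retained.  The
    diagonal is untouched.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    W = _as_array(W).copy()
    P = W.shape[0]
    iu = np.triu_indices(P, k=1)
    mags = np.abs(W[iu])
    n_keep = int(np.ceil(keep_fraction * mags.size))
    cutoff = np.sort(mags)[::-1][n_keep - 1]
    mask = mags >= cutoff
    vals = np.where(mask, W[iu], 0.0)
    out = np.zeros_like(W)
    out[iu] = vals
    out = out + out.T
    np.fill_diagonal(out, np.diag(W))
    return out


def sparse_representation_network(X: np.ndarray, lam: float,
                                  max_iter: int = 10_000,
                                  tol: float = 1e-8,
                                  symmetrize: bool = True) -> np.ndarray:
    """Sparse-representation network by node-wise lasso.

    For each ROI i, solves

        min_{W_i.}  ||x_i - sum_{j != i} W_ij x_j||^2 + lam * sum_{j != i} |W_ij|

    by cyclic coordinate descent, then symmetrises as (W + W^T) / 2 with
    a zero diagonal (``symmetrize=False`` returns the raw per-node
    rows, which satisfy the lasso optimality conditions exactly).
    ``lam`` multiplies the l1 term directly (no 1/2T factor), so grid
    values are on the objective's own scale.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    X = np.asarray(X, dtype=float)
    P, T = X.shape
    W = np.zeros((P, P))
    # sklearn's lasso objective is (1/2T)||y - Aw||^2 + alpha ||w||_1;
    # scaling alpha by lam / (2T) makes it proportional to ours
    model = Lasso(alpha=lam / (2.0 * T), fit_intercept=False,
                  max_iter=max_iter, tol=tol)
    idx = np.arange(P)
    for i in range(P):
        others = idx[idx != i]
        model.fit(X[others].T, X[i])
        if model.n_iter_ >= max_iter:
            import warnings
            warnings.warn(
                f"lasso for ROI {i} hit max_iter={max_iter}; "
                "solution may not satisfy the target tolerance")
        W[i, others] = model.coef_
    return 0.5 * (W + W.T) if symmetrize else W


class PearsonConnectivity(BaseEstimator, TransformerMixin):
    """Transformer from ROI time series to Pearson networks.

    ``transform`` maps an iterable of P x T matrices to an array of
    P x P correlation matrices, optionally thresholded to keep only the
    ``keep_fraction`` strongest edges.
    """

    def __init__(self, keep_fraction: float | None = None):
        self.keep_fraction = keep_fraction

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        out = []
        for subject in X:
            W = pearson_network(subject)
            if self.keep_fraction is not None:
                W = threshold_network(W, self.keep_fraction)
            out.append(W)
        return np.stack(out)


class SparseConnectivity(BaseEstimator, TransformerMixin):
    """Transformer from normalised ROI time series to SR networks."""

    def __init__(self, lam: float = 0.3):
        self.lam = lam

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.stack([
            sparse_representation_network(normalize_roi_signals(s), self.lam)
            for s in X
        ])
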