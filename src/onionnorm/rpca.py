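"""Robust PCA (principal component pursuit) residual normalization.

Decomposes a matrix ``X`` into a low-rank component ``L`` plus a sparse
component ``S`` by solving

    min ||L||_* + lambda * ||S||_1   s.t.  X = L + S

with the inexact augmented-Lagrange-multiplier (IALM) method: singular-value
thresholding on ``L`` and entrywise soft-thresholding on ``S``. In
co-essentiality data the low-rank part absorbs dominant, non-specific signal
(the "reconstructed" data) while the sparse part retains rare, specific
dependencies (the "normalized" data).

The suggested lambda is ``1 / sqrt(max(r, c))``; the onion grid scales it by
a multiplier ``f`` in {0.7, ..., 1.3}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .io import GeneEffectMatrix, NormalizedLayer

#: lambda multiplier grid used for the RPCA onion (RPCO): 7 layers
RPCA_F_GRID: tuple[float, ...] = (0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3)


def default_lambda(r: int, c: int, f: float = 1.0) -> float:
    """Suggested sparsity weight ``f / sqrt(max(r, c))`` for an r x c matrix."""
    if r < 1 or c < 1:
        raise ValueError("matrix dimensions must be positive")
    if f <= 0:
        raise ValueError("f must be positive")
    return f / np.sqrt(max(r, c))


def _soft_threshold(x: np.ndarray, tau: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def _svd_threshold(x: np.ndarray, tau: float) -> tuple[np.ndarray, int]:
    u, s, vt = scipy.linalg.svd(x, full_matrices=False)
    keep = s > tau
    if not keep.any():
        return np.zeros_like(x), 0
    s_shrunk = s[keep] - tau
    return (u[:, keep] * s_shrunk) @ vt[keep], int(keep.sum())


@dataclass
class RpcaResult:
    low_rank: np.ndarray
    sparse: np.ndarray
    lam: float
    iterations: int
    converged: bool
    final_residual: float


class RobustPCA(BaseEstimator):
    """Principal component pursuit via inexact ALM.

    Parameters
    ----------
    lam : float, optional
        Sparsity weight; defaults to ``f / sqrt(max(r, c))`` of the fitted
        matrix.
    f : float
        Multiplier applied to the default lambda when ``lam`` is None.
    tol : float
        Relative Frobenius feasibility tolerance ``||X-L-S||_F / ||X||_F``.
    max_iter : int
        Iteration cap.
    rho : float
        Multiplicative update of the penalty parameter mu per iteration,
        capped at ``1e7 * mu0``. The default 1.0 keeps mu fixed at
        ``r * c / (4 * ||X||_1)``, the convention of the reference
        implementation; aggressive growth (e.g. 1.5) reaches feasibility
        quickly but can stop at a point far from the optimum of the
        convex program, so it is not recommended.

    Attributes
    ----------
    low_rank_, sparse_ : ndarray
        The fitted decomposition (``low_rank_ + sparse_ ~= X``).
    lambda_ : float
        The lambda actually used.
    n_iter_, converged_, final_residual_ :
        Solver diagnostics.

    Notes
    -----
    The solver is fully deterministic: identical inputs and parameters give
    bit-identical outputs. mu0 follows the convention
    ``r * c / (4 * ||X||_1)``.
    """

    def __init__(self, lam: float | None = None, f: float = 1.0,
                 tol: float = 1e-7, max_iter: int = 5000, rho: float = 1.0):
        self.lam = lam
        self.f = f
        self.tol = tol
        self.max_iter = max_iter
        self.rho = rho

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite entries")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        r, c = X.shape
        lam = self.lam if self.lam is not None else default_lambda(r, c, self.f)
        norm_x = np.linalg.norm(X)
        if norm_x == 0:  # all-zero input is trivially decomposed
            self.low_rank_ = np.zeros_like(X)
            self.sparse_ = np.zeros_like(X)
            self.lambda_, self.n_iter_ = lam, 0
            self.converged_, self.final_residual_, self.rank_ = True, 0.0, 0
            return self

        abs_sum = np.abs(X).sum()
        mu = r * c / (4.0 * abs_sum)
        mu_max = mu * 1e7
        # dual initialisation of Lin et al.: Y = X / max(||X||_2, ||X||_inf/lam)
        spectral_norm = scipy.linalg.svdvals(X)[0]
        Y = X / max(spectral_norm, np.abs(X).max() / lam)
        L = np.zeros_like(X)
        S = np.zeros_like(X)
        converged = False
        residual = np.inf
        it = 0
        for it in range(1, self.max_iter + 1):
            L, rank = _svd_threshold(X - S + Y / mu, 1.0 / mu)
            S = _soft_threshold(X - L + Y / mu, lam / mu)
            Z = X - L - S
            residual = np.linalg.norm(Z) / norm_x
            if residual < self.tol:
                converged = True
                break
            Y = Y + mu * Z
            mu = min(mu * self.rho, mu_max)
        self.low_rank_ = L
        self.sparse_ = S
        self.lambda_ = lam
        self.n_iter_ = it
        self.converged_ = converged
        self.final_residual_ = float(residual)
        self.rank_ = int(rank)
        return self

    def fit_transform(self, X, y=None):
        """Fit and return the sparse (normalized) component."""
        return self.fit(X).sparse_

    def result_(self) -> RpcaResult:
        return RpcaResult(self.low_rank_, self.sparse_, self.lambda_,
                          self.n_iter_, self.converged_, self.final_residual_)

    def objective_(self) -> float:
        """Nuclear norm of L plus lambda times the l1 norm of S."""
        return float(scipy.linalg.svdvals(self.low_rank_).sum()
                     + self.lambda_ * np.abs(self.sparse_).sum())


def rpca_decompose(mat: GeneEffectMatrix, lam: float | None = None,
                   tol: float = 1e-7, max_iter: int = 5000) -> RpcaResult:
    """Decompose a labelled matrix in its stored orientation."""
    model = RobustPCA(lam=lam, tol=tol, max_iter=max_iter).fit(mat.values)
    return model.result_()


def rpca_normalize(
    mat: GeneEffectMatrix,
    f: float = 1.0,
    orientation: str | None = None,
    tol: float = 1e-7,
    max_iter: int = 5000,
) -> tuple[NormalizedLayer, NormalizedLayer]:
    """RPCA-normalize a matrix; returns (sparse layer, low-rank layer).

    ``orientation`` selects which axis is treated as rows for the
    decomposition (genes-as-rows for gene networks, samples-as-rows for the
    cell-line network variant); lambda always uses the matrix's own dims so
    the choice does not change lambda.
    """
    work = mat if orientation is None else mat.as_orientation(orientation)
    model = RobustPCA(f=f, tol=tol, max_iter=max_iter).fit(work.values)
    src = mat.content_hash()

    def _layer(values: np.ndarray, method: str) -> NormalizedLayer:
        out = GeneEffectMatrix(values, work.gene_ids, work.sample_ids,
                               orientation=work.orientation,
                               gene_labels=work.gene_labels)
        return NormalizedLayer(matrix=out.as_orientation(mat.orientation),
                               method=method, hyperparameter=f, source_hash=src)

    return _layer(model.sparse_, "rpca"), _layer(model.low_rank_, "rpca_reconstructed")
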