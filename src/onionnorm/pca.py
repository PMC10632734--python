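"""Classical-PCA residual normalization.

The strongest principal components of a gene-effect matrix capture dominant
low-dimensional signal (in DepMap-like data, largely mitochondria-associated
variation). Reconstructing the matrix from its first ``n`` components and
subtracting that reconstruction leaves a residual in which rarer, more
specific co-dependency signal is easier to detect.

Conventions follow R's ``prcomp`` with ``center = scale = TRUE``: variables
are genes (columns of the samples-as-rows matrix), each centered and scaled
to unit variance before the SVD. Both the reconstruction and the residual
live in that standardized coordinate system; downstream Pearson similarity
between gene profiles is invariant to the per-gene affine difference, so the
standardized space is used throughout.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import SAMPLES_AS_ROWS, GeneEffectMatrix, NormalizedLayer

#: hyperparameter grid used for the PCA onion (PCO): 10 layers
PCA_COMPONENT_GRID: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13, 15, 17, 19)


class PCAResidualizer(BaseEstimator, TransformerMixin):
    """Remove the top ``n_components`` principal components from a matrix.

    Parameters
    ----------
    n_components : int
        Number of leading components to reconstruct and subtract.
    center, scale : bool
        Column (variable) centering / unit-variance scaling before the SVD,
        as in ``prcomp(x, center = TRUE, scale = TRUE)``.

    Attributes
    ----------
    loadings_ : ndarray of shape (n_variables, k)
        Orthonormal component loadings (right singular vectors), ordered by
        decreasing explained variance; sign-fixed so the largest-magnitude
        element of each column is positive.
    explained_variance_ : ndarray of shape (k,)
        Variances along each component (non-increasing).
    mean_, scale_ : ndarray of shape (n_variables,)
        Per-variable centers and scales applied before the SVD.
    """

    def __init__(self, n_components: int = 1, center: bool = True, scale: bool = True):
        self.n_components = n_components
        self.center = center
        self.scale = scale

    # -- fitting --------------------------------------------------------------
    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x variables)")
        if np.isnan(X).any():
            raise ValueError("X contains missing values; impute first")
        n, p = X.shape
        self.mean_ = X.mean(axis=0) if self.center else np.zeros(p)
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            if (sd == 0).any():
                bad = np.flatnonzero(sd == 0)[:5].tolist()
                raise ValueError(f"zero-variance variables at indices {bad} with scale=True")
            self.scale_ = sd
        else:
            self.scale_ = np.ones(p)
        Z = (X - self.mean_) / self.scale_
        # prcomp: SVD of the centered/scaled matrix; V columns are loadings
        _, s, vt = scipy.linalg.svd(Z, full_matrices=False)
        V = vt.T
        # deterministic sign: largest-|.| element of each loading positive
        flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])])
        flip[flip == 0] = 1.0
        V *= flip
        self.loadings_ = V
        self.singular_values_ = s
        self.explained_variance_ = s**2 / max(n - 1, 1)
        self.n_components_ = self._check_n(self.n_components)
        return self

    def _check_n(self, n: int) -> int:
        k = self.loadings_.shape[1]
        if not 1 <= n <= k:
            raise ValueError(f"n_components={n} out of range [1, {k}]")
        return int(n)

    def _working(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.scale_

    # -- transforms -----------------------------------------------------------
    def reconstruct(self, X, n_components: int | None = None) -> np.ndarray:
        """Projection of the standardized matrix onto the first n loadings."""
        check_is_fitted(self, "loadings_")
        n = self._check_n(self.n_components if n_components is None else n_components)
        L = self.loadings_[:, :n]
        return self._working(X) @ L @ L.T

    def transform(self, X, n_components: int | None = None) -> np.ndarray:
        """Residual after removing the first n components (standardized space)."""
        check_is_fitted(self, "loadings_")
        return self._working(X) - self.reconstruct(X, n_components)


# -- GeneEffectMatrix-level wrappers ------------------------------------------

def fit_pca(mat: GeneEffectMatrix, center: bool = True, scale: bool = True,
            n_components: int = 1) -> PCAResidualizer:
    """Fit a :class:`PCAResidualizer` on the samples-as-rows view (genes are
    the variables, matching prcomp applied to the distributed CSV)."""
    X = mat.samples_matrix()
    return PCAResidualizer(n_components=n_components, center=center, scale=scale).fit(X)


def pca_reconstruct(mat: GeneEffectMatrix, model: PCAResidualizer,
                    n_components: int | None = None) -> GeneEffectMatrix:
    X = mat.samples_matrix()
    rec = model.reconstruct(X, n_components)
    out = GeneEffectMatrix(rec, mat.gene_ids, mat.sample_ids,
                           orientation=SAMPLES_AS_ROWS, gene_labels=mat.gene_labels)
    return out.as_orientation(mat.orientation)


def pca_normalize(mat: GeneEffectMatrix, n_components: int,
                  center: bool = True, scale: bool = True) -> NormalizedLayer:
    """Remove the first ``n_components`` PCs and return the residual layer."""
    model = fit_pca(mat, center=center, scale=scale, n_components=n_components)
    X = mat.samples_matrix()
    resid = model.transform(X)
    out = GeneEffectMatrix(resid, mat.gene_ids, mat.sample_ids,
                           orientation=SAMPLES_AS_ROWS, gene_labels=mat.gene_labels)
    return NormalizedLayer(
        matrix=out.as_orientation(mat.orientation),
        method="pca",
        hyperparameter=n_components,
        source_hash=mat.content_hash(),
    )
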