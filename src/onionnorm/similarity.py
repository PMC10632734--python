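"""Pearson similarity networks, distances, and scaled exponential affinities.

Profile similarity between genes (or cell lines) is the Pearson correlation
of their effect-score profiles; correlations are turned into distances by
``d = 1 - r`` and then into nonnegative affinities with the scaled
exponential kernel of the similarity-network-fusion framework (the
``affinityMatrix`` convention: a Gaussian density evaluated at the distance,
with a locally adaptive bandwidth built from each node's k-nearest-neighbor
mean distance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import GeneEffectMatrix, NormalizedLayer

logger = logging.getLogger(__name__)


@dataclass
class SimilarityNetwork:
    """Symmetric matrix of Pearson correlations with unit diagonal."""

    weights: np.ndarray
    node_ids: list[str]
    kind: str = "gene"  # or "cell_line"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.node_ids), len(self.node_ids)):
            raise ValueError("weights shape inconsistent with node_ids")
        if not np.isfinite(w).all():
            raise ValueError("non-finite similarity weights")
        self.weights = w


@dataclass
class AffinityNetwork:
    """Symmetric nonnegative kernel weights with positive diagonal."""

    weights: np.ndarray
    node_ids: list[str]
    sigma: float
    k_neighbors: int


def pcc_network(
    layer: NormalizedLayer | GeneEffectMatrix,
    kind: str = "gene",
    max_dropped_fraction: float = 0.1,
) -> SimilarityNetwork:
    """Pearson-correlation network among profiles.

    For ``kind="gene"`` profiles are gene rows (values across conditions);
    for ``kind="cell_line"`` they are sample rows. Zero-variance profiles
    cannot be correlated and are dropped with a warning; more than
    ``max_dropped_fraction`` of them is an error.
    """
    mat = layer.matrix if isinstance(layer, NormalizedLayer) else layer
    if kind == "gene":
        profiles, ids = mat.genes_matrix(), list(mat.gene_ids)
    elif kind == "cell_line":
        profiles, ids = mat.samples_matrix(), list(mat.sample_ids)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 conditions per profile")
    sd = profiles.std(axis=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        if n_dropped > max_dropped_fraction * len(ids):
            raise ValueError(
                f"{n_dropped}/{len(ids)} zero-variance profiles exceed the "
                f"{max_dropped_fraction:.0%} limit"
            )
        dropped = [i for i, k in zip(ids, keep) if not k]
        warnings.warn(f"dropping {n_dropped} zero-variance profiles: {dropped[:5]}...")
        profiles = profiles[keep]
        ids = [i for i, k in zip(ids, keep) if k]
    w = np.corrcoef(profiles)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return SimilarityNetwork(weights=w, node_ids=ids, kind=kind)


def to_distance(net: SimilarityNetwork) -> np.ndarray:
    """Convert correlations to distances: ``d = 1 - r`` (range [0, 2])."""
    d = 1.0 - net.weights
    np.fill_diagonal(d, 0.0)
    return d


def affinity(
    dist: np.ndarray,
    k: int = 5,
    sigma: float = 0.5,
    node_ids: list[str] | None = None,
    eps_floor: float = 1e-12,
) -> AffinityNetwork:
    """Scaled exponential similarity kernel over a distance matrix.

    For each pair (i, j) the local scale is
    ``eps_ij = (mu_i + mu_j + d_ij) / 3`` where ``mu_i`` is the mean of the
    ``k + 1`` smallest distances in column i (the node's k nearest neighbors
    together with its zero self-distance, averaged over ``k + 1`` values —
    the affinityMatrix convention). The affinity is the normal density of
    ``d_ij`` at scale ``sigma * eps_ij``, symmetrized by averaging.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if k <= 0 or k >= n:
        raise ValueError(f"k={k} must be in [1, n-1] for n={n} nodes")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    sorted_cols = np.sort(d, axis=0)
    mu = sorted_cols[: k + 1].mean(axis=0) + np.finfo(float).eps
    eps = (mu[:, None] + mu[None, :] + d) / 3.0
    scale = np.maximum(sigma * eps, eps_floor)
    w = np.exp(-(d**2) / (2.0 * scale**2)) / (scale * np.sqrt(2.0 * np.pi))
    w = (w + w.T) / 2.0
    if node_ids is None:
        node_ids = [str(i) for i in range(n)]
    return AffinityNetwork(weights=w, node_ids=list(node_ids), sigma=sigma, k_neighbors=k)


def affinity_from_similarity(net: SimilarityNetwork, k: int = 5,
                             sigma: float = 0.5) -> AffinityNetwork:
    """Compose ``to_distance`` and ``affinity`` on a similarity network."""
    return affinity(to_distance(net), k=k, sigma=sigma, node_ids=net.node_ids)
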