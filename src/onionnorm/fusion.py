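"""Onion integration: similarity network fusion over normalized layers.

A normalization method run over a grid of hyperparameter values yields a
stack of "layers" — versions of the data with the dominant low-dimensional
signal removed to different extents. Each layer's Pearson network is turned
into an affinity matrix and the stack is fused into a single network by
cross-diffusion (similarity network fusion, SNF): each layer's full kernel
is repeatedly propagated through its own k-nearest-neighbor sparse kernel
against the average of the other layers, which reinforces edges supported by
several layers' neighborhoods and suppresses idiosyncratic ones.

The update for layer v with full kernel ``P_v`` and sparse kernel ``S_v`` is

    P_v  <-  S_v @ mean_{u != v}(P_u) @ S_v.T

followed by re-normalization (off-diagonal rows sum to 1/2, diagonal 1/2)
and symmetrization; the fused network is the re-normalized average of the
final ``P_v``. A simpler elementwise-maximum integration is provided for
the expression-data workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse

from .io import GeneEffectMatrix, NormalizedLayer, ae_preprocess, impute_gene_mean
from .similarity import (AffinityNetwork, SimilarityNetwork,
                         affinity_from_similarity, pcc_network)

#: fusion defaults per normalization method (sigma, k)
METHOD_FUSION_DEFAULTS = {"pca": (0.3, 5), "rpca": (0.5, 5), "ae": (0.5, 5)}


@dataclass
class FusionConfig:
    sigma: float = 0.5
    k_neighbors: int = 5
    iterations: int = 10
    include_unnormalized_layer: bool = False

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @classmethod
    def for_method(cls, method: str, **overrides) -> "FusionConfig":
        sigma, k = METHOD_FUSION_DEFAULTS[method]
        base = dict(sigma=sigma, k_neighbors=k,
                    include_unnormalized_layer=(method == "ae"))
        base.update(overrides)
        return cls(**base)


@dataclass
class FusedNetwork:
    weights: np.ndarray
    node_ids: list[str]
    provenance: list[str] = field(default_factory=list)
    config: FusionConfig | None = None


def _normalize_half(P: np.ndarray) -> np.ndarray:
    """Row normalization with the 1/2-diagonal convention."""
    row = P.sum(axis=1) - np.diag(P)
    row[row == 0] = 1.0
    out = P / (2.0 * row[:, None])
    np.fill_diagonal(out, 0.5)
    return out


def _dominate_set(P: np.ndarray, k: int) -> scipy.sparse.csr_matrix:
    """k-nearest-neighbor sparse kernel: keep the k largest entries per row
    (self excluded; ties at the boundary broken by node order) and normalize
    rows to sum 1."""
    n = P.shape[0]
    W = P.copy()
    np.fill_diagonal(W, -np.inf)
    # argsort is stable: sort by (-weight, node index) for deterministic ties
    order = np.argsort(-W, axis=1, kind="stable")
    keep_idx = order[:, :k]
    rows = np.repeat(np.arange(n), k)
    cols = keep_idx.ravel()
    vals = P[rows, cols]
    S = scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    row_sums = np.asarray(S.sum(axis=1)).ravel()
    row_sums[row_sums == 0] = 1.0
    return scipy.sparse.diags(1.0 / row_sums) @ S


def snf_fuse(layers: list[AffinityNetwork], cfg: FusionConfig) -> FusedNetwork:
    """Fuse affinity layers by cross-diffusion."""
    if len(layers) < 2:
        raise ValueError("need at least 2 layers to fuse")
    node_ids = layers[0].node_ids
    for lay in layers[1:]:
        if lay.node_ids != node_ids:
            raise ValueError("layers must share an identical, ordered node set")
    m = len(layers)
    P = []
    for lay in layers:
        W = np.asarray(lay.weights, dtype=float)
        if (W.sum(axis=1) == 0).any():
            raise ValueError("affinity layer has an all-zero row")
        Pv = _normalize_half(W)
        P.append((Pv + Pv.T) / 2.0)
    S = [_dominate_set(Pv, cfg.k_neighbors) for Pv in P]
    for _ in range(cfg.iterations):
        total = np.add.reduce(P)
        nxt = []
        for v in range(m):
            others = (total - P[v]) / (m - 1)
            # S_v @ others @ S_v.T with the sparse kernel applied from both sides
            Pv = S[v] @ np.asarray(S[v] @ others.T).T
            Pv = _normalize_half(np.asarray(Pv))
            nxt.append((Pv + Pv.T) / 2.0)
        P = nxt
    W = np.add.reduce(P) / m
    W = _normalize_half(W)
    W = (W + W.T + np.eye(len(node_ids))) / 2.0
    return FusedNetwork(weights=W, node_ids=list(node_ids),
                        provenance=[f"affinity(sigma={l.sigma},k={l.k_neighbors})"
                                    for l in layers],
                        config=cfg)


def max_fuse(layers: list[SimilarityNetwork]) -> FusedNetwork:
    """Elementwise-maximum integration of similarity networks."""
    if not layers:
        raise ValueError("no layers to fuse")
    node_ids = layers[0].node_ids
    for lay in layers[1:]:
        if lay.node_ids != node_ids:
            raise ValueError("layers must share an identical, ordered node set")
    W = np.maximum.reduce([lay.weights for lay in layers])
    return FusedNetwork(weights=W, node_ids=list(node_ids),
                        provenance=[f"pcc:{lay.kind}" for lay in layers])


def onion_pipeline(
    mat: GeneEffectMatrix,
    method: str,
    grid: list | None = None,
    cfg: FusionConfig | None = None,
    kind: str = "gene",
    rpca_orientation: str | None = None,
    ae_seed: int = 0,
    ae_epochs: int = 1,
) -> FusedNetwork:
    """Full onion normalization: normalize per grid point, build PCC
    networks, kernelize, and fuse.

    For ``method="ae"`` with ``cfg.include_unnormalized_layer`` (the
    default for AE), the similarity network of the un-normalized data is
    appended as an extra layer before fusion.
    """
    from .ae import AE_LATENT_GRID, AeConfig, ae_normalize
    from .pca import PCA_COMPONENT_GRID, pca_normalize
    from .rpca import RPCA_F_GRID, rpca_normalize

    if method not in ("pca", "rpca", "ae"):
        raise ValueError(f"unknown method {method!r}")
    if cfg is None:
        cfg = FusionConfig.for_method(method)
    if grid is None:
        grid = {"pca": PCA_COMPONENT_GRID, "rpca": RPCA_F_GRID,
                "ae": AE_LATENT_GRID}[method]
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")

    work = impute_gene_mean(mat)
    layers: list[NormalizedLayer] = []
    if method == "pca":
        layers = [pca_normalize(work, int(n)) for n in grid]
    elif method == "rpca":
        layers = [rpca_normalize(work, float(f), orientation=rpca_orientation)[0]
                  for f in grid]
    else:
        pre = ae_preprocess(work)
        for ls in grid:
            ae_cfg = AeConfig(latent_size=int(ls), seed=ae_seed, epochs=ae_epochs)
            layers.append(ae_normalize(pre, ae_cfg, preprocess=False)[0])

    sims = [pcc_network(lay, kind=kind) for lay in layers]
    if cfg.include_unnormalized_layer:
        sims.append(pcc_network(work, kind=kind))
    affs = [affinity_from_similarity(s, k=cfg.k_neighbors, sigma=cfg.sigma)
            for s in sims]
    fused = snf_fuse(affs, cfg)
    fused.provenance = [f"{method}:{g}" for g in grid] + (
        ["unnormalized"] if cfg.include_unnormalized_layer else [])
    return fused
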