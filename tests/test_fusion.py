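"""SNF cross-diffusion against a literal reference; onion pipeline plumbing."""

import numpy as np
import pytest
import scipy.stats

from onionnorm import (AffinityNetwork, FusionConfig, SimilarityNetwork,
                       max_fuse, onion_pipeline, snf_fuse)
from onionnorm.fusion import METHOD_FUSION_DEFAULTS


# -- literal, loop-based reference implementation of the update equations ----

def _normalize_half_ref(P):
    n = P.shape[0]
    out = np.zeros_like(P)
    for i in range(n):
        rs = sum(P[i, j] for j in range(n) if j != i) or 1.0
        for j in range(n):
            out[i, j] = P[i, j] / (2 * rs)
        out[i, i] = 0.5
    return out


def _dominate_ref(P, k):
    n = P.shape[0]
    S = np.zeros_like(P)
    for i in range(n):
        order = sorted(range(n),
                       key=lambda j: (-(P[i, j] if j != i else -np.inf), j))
        for j in order[:k]:
            S[i, j] = P[i, j]
        rs = S[i].sum() or 1.0
        S[i] /= rs
    return S


def _snf_ref(Ws, k, t):
    m = len(Ws)
    P = []
    for W in Ws:
        Pv = _normalize_half_ref(np.array(W, float))
        P.append((Pv + Pv.T) / 2)
    S = [_dominate_ref(Pv, k) for Pv in P]
    for _ in range(t):
        nxt = []
        for v in range(m):
            others = sum(P[u] for u in range(m) if u != v) / (m - 1)
            Pv = S[v] @ others @ S[v].T
            Pv = _normalize_half_ref(Pv)
            nxt.append((Pv + Pv.T) / 2)
        P = nxt
    W = sum(P) / m
    W = _normalize_half_ref(W)
    return (W + W.T + np.eye(W.shape[0])) / 2


def _random_affinities(rng, n, m):
    layers = []
    ids = [f"n{i}" for i in range(n)]
    for _ in range(m):
        A = rng.random((n, n)) + 0.05
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        layers.append(AffinityNetwork(A, ids, sigma=0.5, k_neighbors=3))
    return layers


class TestSnfFuse:
    @pytest.mark.parametrize("n,m,iters", [(6, 2, 1), (10, 3, 3), (12, 3, 2)])
    def test_matches_literal_reference(self, rng, n, m, iters):
        layers = _random_affinities(rng, n, m)
        cfg = FusionConfig(k_neighbors=2 if n == 6 else 3, iterations=iters)
        fused = snf_fuse(layers, cfg)
        ref = _snf_ref([l.weights for l in layers], cfg.k_neighbors, iters)
        np.testing.assert_allclose(fused.weights, ref, atol=1e-10)

    def test_identical_layers_preserve_edge_ranking(self, rng):
        layers = _random_affinities(rng, 10, 1) * 3  # three identical layers
        cfg = FusionConfig(k_neighbors=3, iterations=4)
        fused = snf_fuse(layers, cfg)
        # reference: diffusing the single layer through its own sparse kernel
        single = _snf_ref([layers[0].weights] * 2, 3, 4)
        iu = np.triu_indices(10, k=1)
        rho = scipy.stats.spearmanr(fused.weights[iu], single[iu]).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_output_symmetric_nonnegative(self, rng):
        fused = snf_fuse(_random_affinities(rng, 9, 3),
                         FusionConfig(k_neighbors=3, iterations=5))
        assert (fused.weights >= 0).all()
        np.testing.assert_allclose(fused.weights, fused.weights.T, atol=1e-10)

    def test_layer_order_invariance(self, rng):
        layers = _random_affinities(rng, 8, 3)
        cfg = FusionConfig(k_neighbors=3, iterations=3)
        a = snf_fuse(layers, cfg).weights
        b = snf_fuse(layers[::-1], cfg).weights
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        layers = _random_affinities(rng, 8, 2)
        perm = rng.permutation(8)
        permuted = [AffinityNetwork(l.weights[np.ix_(perm, perm)],
                                    [l.node_ids[i] for i in perm],
                                    l.sigma, l.k_neighbors) for l in layers]
        cfg = FusionConfig(k_neighbors=3, iterations=3)
        a = snf_fuse(layers, cfg).weights
        b = snf_fuse(permuted, cfg).weights
        np.testing.assert_allclose(a[np.ix_(perm, perm)], b, atol=1e-12)

    def test_mismatched_node_sets_rejected(self, rng):
        layers = _random_affinities(rng, 6, 2)
        layers[1].node_ids = [f"x{i}" for i in range(6)]
        with pytest.raises(ValueError, match="node set"):
            snf_fuse(layers, FusionConfig(k_neighbors=2))

    def test_single_layer_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            snf_fuse(_random_affinities(rng, 6, 1), FusionConfig(k_neighbors=2))


class TestMaxFuse:
    def test_single_layer_identity(self, rng):
        W = rng.random((5, 5))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        net = SimilarityNetwork(W, [f"g{i}" for i in range(5)])
        np.testing.assert_array_equal(max_fuse([net]).weights, W)

    def test_elementwise_max_against_enumeration(self, rng):
        ids = [f"g{i}" for i in range(5)]
        stack = []
        for _ in range(5):
            W = rng.uniform(-1, 1, (5, 5))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 1.0)
            stack.append(SimilarityNetwork(W, ids))
        fused = max_fuse(stack)
        for i in range(5):
            for j in range(5):
                assert fused.weights[i, j] == max(s.weights[i, j] for s in stack)


class TestOnionPipeline:
    def test_method_grid_cardinalities(self, tiny_synth):
        mat, _ = tiny_synth
        cfg = FusionConfig.for_method("rpca", iterations=2)
        fused = onion_pipeline(mat, "rpca", cfg=cfg)
        assert len(fused.provenance) == 7
        cfg = FusionConfig.for_method("pca", iterations=2)
        fused = onion_pipeline(mat, "pca", cfg=cfg)
        assert len(fused.provenance) == 10
        cfg = FusionConfig.for_method("ae", iterations=2)
        fused = onion_pipeline(mat, "ae", cfg=cfg, ae_epochs=1)
        assert len(fused.provenance) == 7  # six LS layers plus the raw layer
        assert fused.provenance[-1] == "unnormalized"

    def test_method_fusion_defaults(self):
        assert METHOD_FUSION_DEFAULTS["pca"] == (0.3, 5)
        assert METHOD_FUSION_DEFAULTS["rpca"] == (0.5, 5)
        assert METHOD_FUSION_DEFAULTS["ae"] == (0.5, 5)
        assert FusionConfig().iterations == 10

    def test_empty_grid_rejected(self, tiny_synth):
        mat, _ = tiny_synth
        with pytest.raises(ValueError, match="empty"):
            onion_pipeline(mat, "rpca", grid=[])

    def test_planted_pairs_rank_higher_after_rpco(self, tiny_synth):
        from onionnorm import build_pair_labels, pcc_network, ranked_pairs
        mat, truth = tiny_synth
        std = truth.standard()
        raw = pcc_network(mat)
        fused = onion_pipeline(mat, "rpca",
                               cfg=FusionConfig.for_method("rpca", iterations=5))
        labels = build_pair_labels(std, set(raw.node_ids))
        nonconf = {p for p in labels.positives
                   if not (p[0] in truth.confounder_genes
                           and p[1] in truth.confounder_genes)}

        def median_rank(net):
            entries = ranked_pairs(net, labels)
            rank = {e[0]: r for r, e in enumerate(entries)}
            return np.median([rank[p] for p in nonconf])

        assert median_rank(fused) < median_rank(raw)
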