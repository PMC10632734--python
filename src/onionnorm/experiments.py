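"""Canonical seeded experiments on synthetic data.

These functions bundle the study designs used to validate the pipeline end
to end: confounder removal in gene networks (raw Pearson network versus the
RPCA onion), autoencoder capture of a dominant rank-1 confounder, and
tissue-of-origin prediction from cell-line networks. Each takes a seed and
returns plain dictionaries of measured quantities, so they can be driven
from tests or scripts identically.
"""

from __future__ import annotations

import numpy as np

from .ae import ConvAutoencoder
from .benchmark import build_pair_labels, per_complex_auprc, pr_curve
from .fusion import FusionConfig, onion_pipeline
from .io import ae_preprocess, impute_gene_mean
from .lineage import LabeledNetwork, knn_predict, weighted_prf
from .network import top_edges
from .rpca import RobustPCA
from .similarity import pcc_network
from .synthetic import SynthConfig, SyntheticTruth, generate

#: condition for the autoencoder experiment: a single dominant planted
#: component (most of each confounder gene's variance comes from the factor)
AE_CONDITION = dict(confounder_rank=1, confounder_strength=8.0, noise_sd=0.5)

#: condition for the lineage experiment: strong, sparse lineage dependencies
#: masked by a dominant confounder (the regime the cell-line analysis targets)
LINEAGE_CONDITION = dict(tissue_effect=2.0, confounder_strength=8.0)

#: number of Adam steps roughly matching one epoch at full dependency-map
#: scale when training on the 800-gene synthetic default (see methods note)
SYNTH_AE_EPOCHS = 25


def _confounder_tp_fraction(net, truth: SyntheticTruth, top_n: int = 100) -> float:
    """Fraction of the first ``top_n`` true-positive pairs in the ranking
    whose both members are confounder-set genes."""
    labels = build_pair_labels(truth.standard(), set(net.node_ids))
    curve = pr_curve(net, labels)
    conf = truth.confounder_genes
    tps = [p for p, is_pos in zip(curve.pairs, curve.is_positive) if is_pos]
    tps = tps[:top_n]
    return float(np.mean([a in conf and b in conf for a, b in tps]))


def _median_nonconfounder_auprc(net, truth: SyntheticTruth) -> float:
    table = per_complex_auprc(net, truth.standard())
    vals = [v for cid, v in table.auprc.items()
            if cid not in truth.confounder_complex_ids]
    return float(np.median(vals))


def gene_network_experiment(seed: int, cfg: SynthConfig | None = None) -> dict:
    """Raw Pearson network versus RPCA-onion on the default synthetic data.

    Measures the confounder fraction among the top-100 true positives and
    the median per-complex average precision over non-confounder complexes,
    before and after onion normalization.
    """
    if cfg is None:
        cfg = SynthConfig(seed=seed)
    mat, truth = generate(cfg)
    raw = pcc_network(impute_gene_mean(mat))
    fused = onion_pipeline(mat, "rpca")
    return {
        "raw_confounder_tp_fraction": _confounder_tp_fraction(raw, truth),
        "rpco_confounder_tp_fraction": _confounder_tp_fraction(fused, truth),
        "raw_median_nonconfounder_auprc": _median_nonconfounder_auprc(raw, truth),
        "rpco_median_nonconfounder_auprc": _median_nonconfounder_auprc(fused, truth),
    }


def ae_capture_experiment(seed: int) -> dict:
    """Autoencoder (LS = 1) capture of a dominant rank-1 confounder.

    Measures the mean absolute Pearson correlation between reconstructed
    confounder-gene profiles and the planted cell-line factor, and the
    confounder-pair fraction among the top 500 network edges before and
    after subtracting the reconstruction.
    """
    cfg = SynthConfig(seed=seed, **AE_CONDITION)
    mat, truth = generate(cfg)
    pre = ae_preprocess(impute_gene_mean(mat))
    X = pre.genes_matrix()
    model = ConvAutoencoder(latent_size=1, epochs=SYNTH_AE_EPOCHS, seed=0).fit(X)
    recon = model.reconstruct(X)
    factor = truth.confounder_factors[0]
    conf_idx = [i for i, g in enumerate(pre.gene_ids)
                if g in truth.confounder_genes]
    cors = [abs(np.corrcoef(recon[i], factor)[0, 1]) for i in conf_idx]

    conf = truth.confounder_genes

    def conf_edge_fraction(values):
        from .io import GeneEffectMatrix
        net = pcc_network(GeneEffectMatrix(values, pre.gene_ids, pre.sample_ids))
        edges = top_edges(net, 500).edges
        return float(np.mean([a in conf and b in conf for a, b, _ in edges]))

    return {
        "reconstruction_factor_correlation": float(np.mean(cors)),
        "raw_top_edge_confounder_fraction": conf_edge_fraction(X),
        "ae_top_edge_confounder_fraction": conf_edge_fraction(X - recon),
    }


def lineage_experiment(seed: int, k: int = 5) -> dict:
    """Tissue-of-origin kNN prediction: raw versus RPCA-onion cell-line
    networks under the masked-lineage condition."""
    cfg = SynthConfig(seed=seed, **LINEAGE_CONDITION)
    mat, truth = generate(cfg)
    labels = truth.tissue_labels

    def f1_of(weights, node_ids):
        lnet = LabeledNetwork(weights, list(node_ids), labels)
        preds = knn_predict(lnet, k)
        return weighted_prf(preds, lnet.label_array())["weighted"]["f1"]

    raw = pcc_network(impute_gene_mean(mat), kind="cell_line")
    fused = onion_pipeline(mat, "rpca", kind="cell_line",
                           rpca_orientation="samples_as_rows")
    return {
        "raw_weighted_f1": f1_of(raw.weights, raw.node_ids),
        "rpco_weighted_f1": f1_of(fused.weights, fused.node_ids),
    }


def rpca_recovery_experiment(seed: int, n_trials: int = 5) -> dict:
    """Exact-recovery benchmark: rank-3 plus 5% sparse corruption at 100x60."""
    residuals, errors = [], []
    for trial in range(n_trials):
        rng = np.random.default_rng(seed * 1000 + trial)
        L = (rng.standard_normal((100, 3)) @ rng.standard_normal((3, 60))
             / np.sqrt(3))
        S = np.zeros((100, 60))
        mask = rng.random((100, 60)) < 0.05
        S[mask] = 5.0 * rng.choice([-1.0, 1.0], size=int(mask.sum()))
        X = L + S
        model = RobustPCA(tol=1e-7).fit(X)
        residuals.append(model.final_residual_)
        errors.append(np.linalg.norm(model.low_rank_ - L) / np.linalg.norm(L))
    return {
        "max_relative_residual": float(np.max(residuals)),
        "median_low_rank_error": float(np.median(errors)),
    }
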