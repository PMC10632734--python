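"""Synthetic gene x cell-line fitness matrices with known structure.

The generator emulates the statistical situation the normalization methods
assume: a dominant low-rank confounder whose gene loadings are concentrated
on a designated "mito-like" gene set, sparse within-complex co-essentiality
(each planted complex shares a latent cell-line factor), a weak
tissue-of-origin factor shared by cell lines of the same tissue, Gaussian
noise, and optional missing entries. Ground truth (complex membership,
confounder gene set and loadings, tissue labels) is emitted in exactly the
file dialects the pipeline consumes, so the full workflow is testable
without external downloads.

What it does *not* emulate: DepMap marginals (gene-level essentiality
offsets, screen-quality artifacts, copy-number effects) — see the methods
documentation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .benchmark import CoAnnotationStandard, write_gmt
from .io import ExclusionList, GeneEffectMatrix, write_exclusion_list
from .lineage import write_labels_tsv


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    ``confounder_strength`` is the ratio of the confounder's top singular
    value to the largest singular value of the complex-signal term; values
    above 1 make the confounder the dominant direction of the matrix.
    """

    n_genes: int = 800
    n_cells: int = 120
    n_complexes: int = 25
    complex_size_range: tuple[int, int] = (3, 12)
    n_confounder_complexes: int = 5
    confounder_rank: int = 2
    confounder_gene_fraction: float = 0.15
    confounder_strength: float = 3.0
    complex_effect: float = 1.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    n_tissues: int = 6
    tissue_effect: float = 1.0
    tissue_gene_fraction: float = 0.05
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 < self.confounder_gene_fraction < 1:
            raise ValueError("confounder_gene_fraction must be in (0, 1)")
        if self.n_confounder_complexes > self.n_complexes:
            raise ValueError("n_confounder_complexes exceeds n_complexes")


@dataclass
class SyntheticTruth:
    complexes: dict[str, set[str]]
    confounder_genes: set[str]
    confounder_loadings: np.ndarray  # (n_genes, rank)
    confounder_factors: np.ndarray   # (rank, n_cells)
    tissue_labels: dict[str, str]
    confounder_complex_ids: set[str] = field(default_factory=set)

    def standard(self) -> CoAnnotationStandard:
        return CoAnnotationStandard({k: set(v) for k, v in self.complexes.items()})

    def exclusion(self) -> ExclusionList:
        return ExclusionList(set(self.confounder_genes))


def _draw_complexes(cfg: SynthConfig, rng: np.random.Generator,
                    gene_ids: list[str], confounder_idx: np.ndarray):
    lo, hi = cfg.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_complexes)
    if sizes.sum() > 0.5 * cfg.n_genes:
        raise ValueError(
            f"infeasible config: total complex size {sizes.sum()} exceeds "
            f"half of n_genes={cfg.n_genes}"
        )
    conf_pool = list(confounder_idx)
    other_pool = [i for i in range(cfg.n_genes) if i not in set(confounder_idx)]
    rng.shuffle(conf_pool)
    rng.shuffle(other_pool)
    complexes: dict[str, list[int]] = {}
    conf_ids: set[str] = set()
    for c, size in enumerate(sizes):
        cid = f"CPX{c + 1:03d}"
        pool = conf_pool if c < cfg.n_confounder_complexes else other_pool
        if cfg.allow_overlap:
            members = list(rng.choice(pool if pool else range(cfg.n_genes),
                                      size=size, replace=False))
        else:
            if len(pool) < size:
                raise ValueError(f"infeasible config: gene pool exhausted at {cid}")
            members = [pool.pop() for _ in range(int(size))]
        complexes[cid] = members
        if c < cfg.n_confounder_complexes:
            conf_ids.add(cid)
    return complexes, conf_ids


def generate(cfg: SynthConfig) -> tuple[GeneEffectMatrix, SyntheticTruth]:
    """Generate a matrix plus ground truth; fully determined by cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    gene_labels = [f"{g} ({i + 1})" for i, g in enumerate(gene_ids)]
    sample_ids = [f"ACH-{i + 1:06d}" for i in range(cfg.n_cells)]

    n_conf = int(round(cfg.confounder_gene_fraction * cfg.n_genes))
    confounder_idx = rng.choice(cfg.n_genes, size=n_conf, replace=False)
    complexes_idx, conf_ids = _draw_complexes(cfg, rng, gene_ids, confounder_idx)

    # within-complex co-essentiality: one latent cell factor per complex
    complex_term = np.zeros((cfg.n_genes, cfg.n_cells))
    for members in complexes_idx.values():
        factor = rng.standard_normal(cfg.n_cells)
        complex_term[members, :] += cfg.complex_effect * factor

    # low-rank confounder concentrated on the confounder gene set
    U = np.zeros((cfg.n_genes, cfg.confounder_rank))
    U[confounder_idx, :] = rng.standard_normal((n_conf, cfg.confounder_rank))
    V = rng.standard_normal((cfg.confounder_rank, cfg.n_cells))
    confounder_term = U @ V
    s_complex = scipy.linalg.svdvals(complex_term)[0] if cfg.complex_effect > 0 else 1.0
    s_conf = scipy.linalg.svdvals(confounder_term)[0]
    if s_conf > 0:
        scale = cfg.confounder_strength * s_complex / s_conf
        confounder_term *= scale
        U = U * scale

    # weak tissue-of-origin structure among cell lines: each tissue has a
    # sparse set of lineage-dependency genes (emulating lineage-specific
    # essentialities, which are sparse in the gene dimension and therefore
    # survive in the sparse component of a low-rank/sparse decomposition)
    tissues = np.array([f"tissue_{(i % cfg.n_tissues) + 1}" for i in range(cfg.n_cells)])
    rng.shuffle(tissues)
    tissue_term = np.zeros((cfg.n_genes, cfg.n_cells))
    n_tissue_genes = max(1, int(round(cfg.tissue_gene_fraction * cfg.n_genes)))
    non_conf = np.array([i for i in range(cfg.n_genes) if i not in set(confounder_idx)])
    for t in np.unique(tissues):
        mask = tissues == t
        genes_t = rng.choice(non_conf, size=min(n_tissue_genes, non_conf.size),
                             replace=False)
        tissue_term[np.ix_(genes_t, mask)] += (
            cfg.tissue_effect * rng.standard_normal(genes_t.size)[:, None])

    X = confounder_term + complex_term + tissue_term
    X += cfg.noise_sd * rng.standard_normal(X.shape)

    if cfg.missing_rate > 0:
        mask = rng.random(X.shape) < cfg.missing_rate
        X = X.copy()
        X[mask] = np.nan

    if cfg.confounder_strength > 1 and cfg.complex_effect > 0 and n_conf > 0:
        # the confounder must be the dominant direction of the clean signal
        u1 = scipy.linalg.svd(np.nan_to_num(X), full_matrices=False)[0][:, 0]
        q, _ = np.linalg.qr(U)
        proj = np.linalg.norm(q.T @ u1)
        if proj < 0.5:
            raise RuntimeError(
                f"confounder is not the top singular direction (projection {proj:.2f}); "
                "config violates its own confounder_strength contract"
            )

    mat = GeneEffectMatrix(X, gene_ids, sample_ids, orientation="genes_as_rows",
                           gene_labels=gene_labels)
    truth = SyntheticTruth(
        complexes={cid: {gene_ids[i] for i in members}
                   for cid, members in complexes_idx.items()},
        confounder_genes={gene_ids[i] for i in confounder_idx},
        confounder_loadings=U,
        confounder_factors=V,
        tissue_labels={sid: t for sid, t in zip(sample_ids, tissues)},
        confounder_complex_ids=conf_ids,
    )
    return mat, truth


def write_truth(truth: SyntheticTruth, directory) -> dict[str, str]:
    """Emit ground-truth files in the dialects the pipeline consumes.

    Writes a GMT co-annotation standard, a plain-text exclusion list, a
    tissue-label TSV and a confounder-loadings CSV; returns the paths.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "standard_gmt": os.path.join(directory, "standard.gmt"),
        "exclusion_txt": os.path.join(directory, "exclusion.txt"),
        "tissue_tsv": os.path.join(directory, "tissue_labels.tsv"),
        "loadings_csv": os.path.join(directory, "confounder_loadings.csv"),
    }
    write_gmt(truth.standard(), paths["standard_gmt"])
    write_exclusion_list(truth.exclusion(), paths["exclusion_txt"])
    write_labels_tsv(truth.tissue_labels, paths["tissue_tsv"])
    n_genes, rank = truth.confounder_loadings.shape
    df = pd.DataFrame(truth.confounder_loadings,
                      columns=[f"factor_{r + 1}" for r in range(rank)])
    df.insert(0, "gene_index", np.arange(n_genes))
    df.to_csv(paths["loadings_csv"], index=False)
    return paths
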