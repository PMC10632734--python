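# onionnorm

Normalization and integration tools for extracting functional gene networks
from genome-wide CRISPR fitness screens.

Profile similarity (co-essentiality) between genes in dependency-map data is
a powerful signal of shared function, but it is dominated by a strong
low-dimensional component — largely mitochondria-associated variation — that
masks relationships within smaller protein complexes. `onionnorm` treats that
dominant low-dimensional signal as the thing to *remove*: a dimensionality
reduction method reconstructs the data from its strongest low-dimensional
structure, the reconstruction is subtracted, and similarity networks are
built from the residual. Because different hyperparameter settings expose
different relationships, the package also implements "onion" normalization:
the same data normalized over a grid of settings yields a stack of layers
whose similarity networks are fused into a single network with similarity
network fusion (SNF).

## Methods at a glance

- **PCA normalization.** With column-standardized data `M` (cell lines ×
  genes) and loadings `L` from an SVD, the reconstruction from the first `n`
  components is `M_rec = M L_n L_nᵀ` and the normalized data are
  `M_norm = M − M_rec`. Grid: `n ∈ {1, 3, 5, …, 19}` (10 layers).
- **Robust PCA (principal component pursuit).** Decompose `X = L + S` by
  minimizing `‖L‖* + λ‖S‖₁`, solved with an inexact augmented-Lagrangian
  iteration (singular-value thresholding on `L`, soft thresholding on `S`).
  `S` is the normalized data, `L` the reconstruction;
  `λ = f / √max(r, c)` with `f ∈ {0.7, …, 1.3}` (7 layers).
- **Autoencoder normalization.** A 1D convolutional autoencoder
  (conv 1→10 → maxpool → conv 10→20 → maxpool → linear bottleneck of width
  *LS*, mirrored decoder with max-unpooling and transposed convolutions,
  kernel size 3, pooling size 2) is trained on preprocessed gene profiles;
  the reconstruction is subtracted. Grid: `LS ∈ {1, 2, 3, 4, 5, 10}`
  (6 layers, plus the un-normalized network as a 7th layer when fusing).
  Implemented in pure numpy with manual backpropagation and Adam; fully
  seeded and reproducible.
- **Onion fusion.** Each layer's Pearson network is converted to distances
  (`d = 1 − r`), kernelized with the scaled exponential affinity kernel, and
  fused by SNF cross-diffusion (`P_v ← S_v · mean_{u≠v}(P_u) · S_vᵀ`, with
  row re-normalization and symmetrization each round). Defaults: σ = 0.3,
  k = 5 for the PCA onion; σ = 0.5, k = 5 for the RPCA and AE onions;
  10 iterations.
- **Evaluation.** Co-annotation benchmarking against a protein-complex
  standard: precision vs. absolute true positives, complex contribution
  diversity, per-complex average precision, threshold-crossing counts by
  complex size, and exclusion of pairs whose both members sit on an
  exclusion list (mitochondria-like genes). Plus top-N-edge network
  statistics and a leave-one-out kNN tissue-of-origin classifier for
  cell-line networks.

A seeded synthetic generator (`onionnorm.synthetic`) produces gene ×
cell-line matrices with a planted low-rank confounder concentrated on a
designated gene set, sparse within-complex signal, sparse tissue factors,
noise and missingness — together with ground-truth files in the exact
dialects the pipeline consumes — so every stage is testable without
external downloads.

## Worked example

```python
import numpy as np
from onionnorm import (SynthConfig, generate, impute_gene_mean, pcc_network,
                       onion_pipeline, build_pair_labels, per_complex_auprc,
                       pr_curve)

cfg = SynthConfig(n_genes=800, n_cells=120, seed=1)
mat, truth = generate(cfg)

raw = pcc_network(impute_gene_mean(mat))          # Pearson co-essentiality
rpco = onion_pipeline(mat, "rpca")                # 7 RPCA layers + SNF

std = truth.standard()
for name, net in [("raw", raw), ("RPCO", rpco)]:
    labels = build_pair_labels(std, set(net.node_ids))
    curve = pr_curve(net, labels)
    tps = [p for p, pos in zip(curve.pairs, curve.is_positive) if pos][:100]
    conf = np.mean([a in truth.confounder_genes and b in truth.confounder_genes
                    for a, b in tps])
    table = per_complex_auprc(net, std)
    med = np.median([v for c, v in table.auprc.items()
                     if c not in truth.confounder_complex_ids])
    print(f"{name:>4}: confounder fraction of top-100 TPs = {conf:.2f}, "
          f"median non-confounder complex AUPRC = {med:.3f}")
```

Output:

```
 raw: confounder fraction of top-100 TPs = 0.27, median non-confounder complex AUPRC = 0.035
RPCO: confounder fraction of top-100 TPs = 0.06, median non-confounder complex AUPRC = 0.073
```

In the raw Pearson network, more than a quarter of the strongest true-
positive pairs come from the planted confounder gene set; after RPCA-onion
normalization that share collapses while the recovery of the remaining
(non-confounder) complexes roughly doubles — the behaviour the method is
designed to deliver.

The same pipeline is available from the shell:

```bash
onion simulate --seed 1 --out sim/
onion fuse sim/gene_effect.csv --method rpca --out fused/
onion benchmark sim/gene_effect.csv sim/standard.gmt \
      --exclusion sim/exclusion.txt --out bench/
onion knn sim/gene_effect.csv sim/tissue_labels.tsv --k 5 --out knn/
```

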