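# Methods

This note documents the models implemented in `onionnorm`, the parameter
choices that matter, the synthetic data the tests run on, and what the
package's experiments do and do not establish.

## The normalization problem

Gene-level fitness profiles from pooled CRISPR screens correlate strongly
when genes work together, but the correlation structure of dependency-map
style data is dominated by one strong low-dimensional component, largely
aligned with mitochondria-associated genes and plausibly driven by
technical or non-specific variation. Two assumptions motivate removing it:
true genetic dependencies are rare (an average gene interacts with a few
percent of the genome), so functional signal should be sparse; and the
dominant low-dimensional signal is shared by so many genes that it is
uninformative about specific complexes. All three normalizers implement the
same scheme: fit a low-dimensional representation, reconstruct the data
from it, subtract the reconstruction.

## PCA residualization

`PCAResidualizer` follows the semantics of an SVD-based PCA with variables
centered and scaled (genes are the variables, i.e. columns of the cell-line
× gene matrix). The reconstruction from `n` components is
`Z L_n L_nᵀ` where `Z` is the standardized matrix and `L` the loadings;
the normalized layer is `Z − Z L_n L_nᵀ`, returned in the standardized
coordinate system. Working in the standardized space is deliberate:
subtracting the reconstruction in raw units differs only by a per-gene
affine transform, to which the downstream Pearson similarity is invariant,
and the standardized convention is self-consistent with multiplying the
standardized scores by the rotation matrix. Loadings get a deterministic
sign (largest-magnitude element positive); the choice only stabilizes
serialization. Zero-variance genes are an error when scaling is on.

## Robust PCA (principal component pursuit)

`RobustPCA` solves `min ‖L‖* + λ‖S‖₁ s.t. X = L + S` by the inexact
augmented-Lagrangian method: alternately apply singular-value thresholding
at `1/μ` to `X − S + Y/μ` and entrywise soft thresholding at `λ/μ` to
`X − L + Y/μ`, then update the multiplier `Y ← Y + μ(X − L − S)`. Defaults:

- `λ = f / √max(r, c)`, `f = 1` unless a grid is requested;
- `μ = r·c / (4‖X‖₁)`, **held fixed** (`rho = 1.0`). A growing penalty
  (e.g. ρ = 1.5 per iteration) reaches feasibility in fewer iterations but
  can stop far from the optimum of the convex program — on planted rank-3
  instances the low-rank recovery error degrades from ~1e-7 to ~0.5 — so
  penalty growth is available but off by default;
- termination at relative Frobenius feasibility `‖X − L − S‖_F/‖X‖_F <
  1e-7`, cap 5000 iterations; a `converged_` flag records which fired.

The solver contains no randomness: identical inputs give bit-identical
outputs. Note the direction of the λ tradeoff: *larger* λ makes the sparse
term costlier, so more of the matrix moves into `L` (higher rank,
reconstruction closer to the input); smaller λ empties `L`. The f grid
0.7–1.3 therefore spans reconstructions from lean to near-complete.

Orientation is an explicit argument, never inferred: gene networks
decompose the genes × cell-lines arrangement, the cell-line analysis the
transpose. The decomposition itself is transpose-equivariant (λ uses
`max(r, c)`), so this only affects which axis downstream code correlates.

## Autoencoder residualization

`ConvAutoencoder` is an hourglass network over gene profiles (one channel,
length = number of cell lines): conv(1→10, k3, pad 1) → maxpool(2) →
conv(10→20, k3, pad 1) → maxpool(2) → flatten → linear(→LS), mirrored by
linear → unflatten → max-unpool → transposed conv(20→10) → max-unpool →
transposed conv(10→1) → final linear restoring the profile length.
Max-unpooling reuses the encoder's pooling indices. With stride 1 and
symmetric padding a transposed convolution is the correlation with the
flipped, channel-transposed kernel — the same parameterized linear map as a
convolution — and is implemented as such.

Training is mini-batch Adam (lr 1e-3, batch 64) on mean squared
reconstruction error; loss, optimizer and batch size are not fixed by the
architecture and are exposed in `AeConfig`. Everything is seeded: parameter
initialisation and epoch shuffling come from one generator, so two runs
with the same seed agree to machine precision. The default of one training
epoch is calibrated to full dependency-map scale (~18k profiles ≈ 280 Adam
steps at batch 64); on the 800-gene synthetic data the canonical
experiments use 25 epochs (~325 steps) to hold the optimisation budget
comparable rather than the epoch count.

Preprocessing before training (`ae_preprocess`): per-gene standardization
(population SD), clipping of z-scores at ±4, then one global min-max map
onto [−1, 1]. The residual layer is computed against this preprocessed
matrix, because the reconstruction lives in the preprocessed value space;
Pearson similarity downstream is again invariant to the per-gene affine
difference from raw units.

A structural caveat worth knowing: the max-unpool indices carry per-sample
information around the bottleneck, so even at LS = 1 the reconstruction is
not a pure rank-1 function of the input — it tracks individual profiles
more closely than an SVD rank-1 fit would. This is faithful to the
architecture; it means the autoencoder isolates a planted component well
only when that component dominates individual profiles, not merely the
matrix norm.

## Similarity, affinity, fusion

Similarity is the Pearson correlation of profiles; zero-variance profiles
are dropped with a warning (error if more than 10% drop). Distance is
`d = 1 − r`. The affinity kernel reproduces the SNF convention exactly: the
local scale is `ε_ij = (μ_i + μ_j + d_ij)/3`, where `μ_i` is the mean of
the k+1 smallest entries of column i — the k nearest neighbors together
with the zero self-distance, averaged over k+1 values — and the weight is
the normal density of `d_ij` at scale `σ·ε_ij`, symmetrized. ε is floored
at 1e-12 so duplicate points cannot divide by zero; neighbor ties break by
node order.

`snf_fuse` implements cross-diffusion: full kernels are row-normalized with
the ½-diagonal convention (off-diagonal rows sum to ½, diagonal ½) and
symmetrized; sparse kernels keep each row's k largest entries (self
excluded, ties by node order) row-normalized to 1; each round updates every
layer as `P_v ← S_v · mean_{u≠v}(P_u) · S_vᵀ` followed by re-normalization
and symmetrization; the output is the re-normalized, symmetrized average of
the final kernels. A literal loop-based implementation of the same
equations lives in the test suite and pins the vectorized version to 1e-10.
Defaults follow the published settings: σ = 0.3, k = 5 for the PCA onion,
σ = 0.5, k = 5 for the RPCA and AE onions, 10 iterations; the AE onion
additionally fuses the un-normalized network as a seventh layer, passed
through the same (σ, k) kernel as the normalized layers. The expression
workflow instead integrates layers by the elementwise maximum
(`max_fuse`).

## Benchmarking

Pairs of genes that share at least one complex in the standard are
positives; pairs of standard genes sharing none are negatives; pairs whose
*both* members are on the exclusion list take part in nothing. Ranking is
by descending weight with a lexicographic pair-id tie-break, so every
output is deterministic and invariant under strictly increasing transforms
of the weights. The precision curve is reported against the absolute
true-positive count (recall is also emitted; it differs only by a constant
factor). Contribution diversity takes, at each precision cutoff, the
longest ranking prefix whose running precision still meets the cutoff and
attributes each true positive fractionally (1/m to each of the m complexes
containing it), so fractions sum to one; the top 10 complexes by overall
contribution are named, the rest pooled as "other". Per-complex AUPRC is
step-interpolated average precision with that complex's internal pairs as
positives and the internal pairs of *other* complexes as negatives.
Threshold-crossing counts classify complexes as boosted (raw < t ≤
normalized) or weakened (normalized < t ≤ raw) per size bin
{2–3, 4–5, 6–9, ≥10}.

## Network and lineage analysis

Top-N edge networks take the N largest unordered pairs (deterministic
tie-break); connected components are the clusters; the cluster score is the
mean within-cluster edge weight standardized against the mean and SD of all
off-diagonal weights — this statistic is a package definition, chosen
because the quantity it summarizes (how much a cluster's internal weights
stand out from the network background) is what the downstream analysis
needs; other backgrounds are possible. The kNN tissue classifier is
leave-one-out on a precomputed cell-line similarity network: majority vote
among the K most similar other cell lines, voting ties resolved by the
single most similar neighbor, neighbor ranking ties by node order. Overall
precision/recall/F1 are support-weighted means of per-class scores (a class
never predicted gets precision 0); the baseline classifier draws labels
uniformly from the observed label multiset, averaged over (by default) 100
seeded iterations. All classes participate regardless of support.

## Synthetic data

`generate(SynthConfig)` draws, in order: disjoint complexes (sizes uniform
in a range; a configurable number of them live inside the confounder gene
set, mimicking mitochondria-associated complexes), a shared latent
cell-line factor per complex (loading `complex_effect` on every member), a
rank-R confounder whose gene loadings are nonzero only on a designated
fraction of genes and whose top singular value is `confounder_strength`
times that of the complex signal, sparse tissue factors (each tissue
perturbs a random ~5% subset of non-confounder genes for its cell lines —
lineage-specific dependencies are sparse in the gene dimension, which is
exactly why they survive in the sparse component of a low-rank/sparse
decomposition), Gaussian noise, and an independent uniform missingness
mask. Generation asserts post hoc that the confounder is the top singular
direction whenever `confounder_strength > 1`.

Defaults are sized for desk-scale runs: 800 genes × 120 cell lines, 25
complexes of 3–12 genes (5 inside the confounder set), rank-2 confounder
over 15% of genes at strength 3, complex effect 1, tissue effect 1 over 6
tissues, noise SD 1, no missingness, all under one seed; an end-to-end
normalization-plus-benchmark run completes in seconds.

Two canonical experiment conditions deviate from the defaults and are
defined once in `onionnorm.experiments`:

- **Dominant-component condition** (autoencoder experiment): rank-1
  confounder at strength 8 with noise SD 0.5, making the factor account for
  ~70% of each confounder gene's variance. The autoencoder premise — a
  single bottleneck node captures the dominant signal — refers to signal
  dominant at the level of individual profiles, which the default strength
  does not produce (see the unpooling caveat above).
- **Masked-lineage condition** (kNN experiment): tissue effect 2 and
  confounder strength 8, so the raw cell-line network is confounder-masked
  (near-baseline F1) while strong sparse lineage dependencies survive RPCA
  — the regime the cell-line analysis addresses.

What the generator does *not* emulate: dependency-map marginals (gene-level
essentiality offsets), screen-quality and copy-number artifacts, overlapping
complex membership (off by default, available via a flag), or realistic
complex-size and tissue-size distributions. Passing tests therefore
demonstrate the algorithms' correctness and the direction of their effects
under the planted model, not performance magnitudes on real screens.

## Numerical choices and degenerate inputs

- Imputation replaces missing values by gene-wise means of observed
  entries; a fully missing gene is an error, observed entries are preserved
  bit-for-bit, and re-imputation is a no-op.
- Expression QC masks (gene detected in more than `min_nonzero_cells`
  cells; cells with gene counts strictly inside the bounds and mitochondrial
  read percentage strictly below the cutoff) are computed jointly on the
  input and applied in one pass, matching single-pass QC semantics; on
  pathological inputs a second pass could remove more.
- The SNF half-diagonal normalization treats an all-zero off-diagonal row
  as sum 1 to avoid division by zero; affinity layers with an all-zero row
  are rejected outright.
- Pearson similarity matrices are clipped to [−1, 1] and symmetrized before
  use; fused networks carry a 0.5-ish diagonal that every consumer ignores
  (rankings and kNN exclude self-pairs).
- All stochastic components (generator, autoencoder, baseline classifier)
  take explicit integer seeds; the solvers are deterministic.

## Known limitations

- The autoencoder needs profile lengths of at least twice the squared
  pooling size (two pooling stages); very small screens cannot use it.
- SNF cross-diffusion with small node sets (≲100) and small k can wash out
  weak per-layer signal; the fused network is at its best when individual
  layers already rank informative edges highly.
- Per-complex average precision is computed over within-standard pairs
  only, so it is insensitive to how a network ranks pairs outside the
  standard.
- The cell-line workflow assumes one label per cell line and evaluates
  leave-one-out; no train/test split or label-scarcity handling is
  implemented.
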