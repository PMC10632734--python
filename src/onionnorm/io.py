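"""Core data containers, file dialects and preprocessing transforms.

The central container is :class:`GeneEffectMatrix`, a labelled real matrix of
gene fitness-effect scores (CERES/Chronos-like) or log-expression values.
DepMap-style gene-effect CSVs store cell lines as rows and ``"SYMBOL (ID)"``
gene columns; the package's canonical in-memory orientation is genes-as-rows,
because every downstream statistic (gene-wise imputation, per-gene
standardization, gene-gene Pearson similarity) is gene-wise.
"""

from __future__ import annotations

import gzip
import hashlib
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

GENES_AS_ROWS = "genes_as_rows"
SAMPLES_AS_ROWS = "samples_as_rows"


class ParseError(ValueError):
    """Raised when an input file does not conform to its dialect."""


@dataclass
class GeneEffectMatrix:
    """Gene x condition real matrix with axis labels.

    Parameters
    ----------
    values : ndarray
        2-D float array. Rows are genes when ``orientation`` is
        ``"genes_as_rows"``, otherwise rows are samples (cell lines / cells).
    gene_ids, sample_ids : list of str
        Ordered unique axis labels.
    orientation : str
        Either ``"genes_as_rows"`` or ``"samples_as_rows"``.
    gene_labels : list of str, optional
        Original on-disk column headers (e.g. ``"A1BG (1)"``), kept so a
        round-trip through the CSV dialect preserves headers exactly.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    orientation: str = GENES_AS_ROWS
    gene_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n_rows, n_cols = self.values.shape
        if self.orientation == GENES_AS_ROWS:
            exp = (len(self.gene_ids), len(self.sample_ids))
        elif self.orientation == SAMPLES_AS_ROWS:
            exp = (len(self.sample_ids), len(self.gene_ids))
        else:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if (n_rows, n_cols) != exp:
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples "
                f"under orientation {self.orientation!r}"
            )
        for name, ids in (("gene_ids", self.gene_ids), ("sample_ids", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"{name} contains duplicates")

    # -- orientation handling -------------------------------------------------
    def as_orientation(self, orientation: str) -> "GeneEffectMatrix":
        """Return a view-like copy in the requested orientation."""
        if orientation == self.orientation:
            return self
        return replace(self, values=self.values.T, orientation=orientation)

    def genes_matrix(self) -> np.ndarray:
        """Values with genes as rows, regardless of stored orientation."""
        return self.as_orientation(GENES_AS_ROWS).values

    def samples_matrix(self) -> np.ndarray:
        return self.as_orientation(SAMPLES_AS_ROWS).values

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def copy(self) -> "GeneEffectMatrix":
        return replace(self, values=self.values.copy())

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.values).tobytes())
        h.update("\x00".join(self.gene_ids).encode())
        h.update("\x00".join(self.sample_ids).encode())
        return h.hexdigest()[:16]


@dataclass
class NormalizedLayer:
    """A normalized version of a source matrix plus provenance.

    ``method`` is one of ``{"pca", "rpca", "rpca_reconstructed", "ae",
    "ae_reconstructed", "none"}``; ``hyperparameter`` is the grid value that
    produced it (number of removed PCs, the lambda multiplier f, or the
    autoencoder latent size LS).
    """

    matrix: GeneEffectMatrix
    method: str = "none"
    hyperparameter: float | int | None = None
    source_hash: str = ""

    @property
    def values(self) -> np.ndarray:
        return self.matrix.values


@dataclass
class ExclusionList:
    """Set of gene ids whose within-set pairs are dropped from evaluation."""

    gene_ids: set[str] = field(default_factory=set)

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_ids

    def __len__(self) -> int:
        return len(self.gene_ids)


# -- DepMap-style CSV dialect -------------------------------------------------

def _dedupe(names: list[str]) -> list[str]:
    """Make duplicate names unique by suffixing ``.1``, ``.2`` ... (R style)."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            new = f"{name}.{seen[name]}"
            logger.warning("duplicate gene id %r renamed to %r", name, new)
            out.append(new)
            seen.setdefault(new, 0)
        else:
            seen[name] = 0
            out.append(name)
    return out


def _symbol(label: str) -> str:
    """Extract the gene symbol from a ``"SYMBOL (EntrezID)"`` header."""
    return label.split(" (")[0] if " (" in label else label


def read_gene_effect_csv(
    path: str | os.PathLike,
    orientation_hint: str = SAMPLES_AS_ROWS,
) -> GeneEffectMatrix:
    """Read a DepMap-style gene-effect CSV.

    On disk the first column holds sample (cell line) IDs and the remaining
    headers are ``"SYMBOL (EntrezID)"`` gene labels; empty cells and ``NA``
    are missing values. The returned matrix is in the canonical
    genes-as-rows orientation unless ``orientation_hint`` says otherwise.
    """
    try:
        df = pd.read_csv(path, index_col=0, na_values=["NA"], keep_default_na=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"malformed gene-effect CSV {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: zero samples or zero genes")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric column {non_numeric[0]!r}")
    gene_labels = [str(c) for c in df.columns]
    gene_ids = _dedupe([_symbol(c) for c in gene_labels])
    sample_ids = _dedupe([str(i) for i in df.index])
    mat = GeneEffectMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        orientation=SAMPLES_AS_ROWS,
        gene_labels=gene_labels,
    )
    return mat.as_orientation(orientation_hint)


def write_gene_effect_csv(mat: GeneEffectMatrix, path: str | os.PathLike) -> None:
    """Write the DepMap-style dialect (samples as rows, gene-label headers)."""
    m = mat.as_orientation(SAMPLES_AS_ROWS)
    cols = m.gene_labels if m.gene_labels is not None else m.gene_ids
    df = pd.DataFrame(m.values, index=m.sample_ids, columns=cols)
    df.to_csv(path)


def read_exclusion_list(path: str | os.PathLike) -> ExclusionList:
    """Read a plain-text one-gene-per-line exclusion list."""
    with open(path) as fh:
        genes = {line.strip() for line in fh if line.strip()}
    return ExclusionList(gene_ids=genes)


def write_exclusion_list(excl: ExclusionList, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in sorted(excl.gene_ids):
            fh.write(g + "\n")


# -- imputation and autoencoder preprocessing ---------------------------------

def impute_gene_mean(mat: GeneEffectMatrix) -> GeneEffectMatrix:
    """Replace missing entries by the mean of the gene's observed values.

    Observed entries are preserved bit-for-bit; a gene with no observed value
    at all is an error (its mean is undefined).
    """
    g = mat.as_orientation(GENES_AS_ROWS)
    values = g.values.copy()
    missing = np.isnan(values)
    if not missing.any():
        return mat.copy()
    all_missing = missing.all(axis=1)
    if all_missing.any():
        bad = [g.gene_ids[i] for i in np.flatnonzero(all_missing)]
        raise ValueError(f"genes with all values missing: {bad}")
    with np.errstate(invalid="ignore"):
        gene_means = np.nanmean(values, axis=1)
    rows, cols = np.nonzero(missing)
    values[rows, cols] = gene_means[rows]
    out = replace(g, values=values)
    return out.as_orientation(mat.orientation)


def ae_preprocess(mat: GeneEffectMatrix, clip: float = 4.0) -> GeneEffectMatrix:
    """Prepare a matrix for autoencoder training.

    Chain: per-gene standardization (z-scores over conditions), clipping of
    z-scores to ``[-clip, clip]``, then a single global min-max map onto
    ``[-1, 1]``. Requires an already-imputed matrix.
    """
    g = mat.as_orientation(GENES_AS_ROWS)
    values = g.values
    if np.isnan(values).any():
        raise ValueError("ae_preprocess requires an imputed matrix (no NaN)")
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = [g.gene_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant gene profiles (sd=0): {bad}")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    z = np.clip(z, -clip, clip)
    lo, hi = z.min(), z.max()
    if hi == lo:
        raise ValueError("degenerate matrix: all z-scores identical")
    scaled = 2.0 * (z - lo) / (hi - lo) - 1.0
    out = replace(g, values=scaled)
    return out.as_orientation(mat.orientation)


# -- scRNA-seq pathway: MTX reading, QC filters, log-normalization ------------

def _open_maybe_gz(directory: str, names: tuple[str, ...]):
    for name in names:
        p = os.path.join(directory, name)
        if os.path.exists(p):
            return gzip.open(p, "rt") if name.endswith(".gz") else open(p)
    raise ParseError(f"none of {names} found in {directory}")


def read_counts_mtx(directory: str | os.PathLike) -> GeneEffectMatrix:
    """Read a Cell Ranger MTX triplet directory (plain or gzipped).

    Expects ``matrix.mtx[.gz]`` (genes x cells), ``features.tsv[.gz]`` or
    ``genes.tsv[.gz]`` (gene symbol in the second column when present) and
    ``barcodes.tsv[.gz]``. Counts must be nonnegative.
    """
    directory = str(directory)
    mtx_path = None
    for name in ("matrix.mtx", "matrix.mtx.gz"):
        p = os.path.join(directory, name)
        if os.path.exists(p):
            mtx_path = p
            break
    if mtx_path is None:
        raise ParseError(f"matrix.mtx[.gz] not found in {directory}")
    counts = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(counts):
        counts = counts.toarray()
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ParseError("negative counts in matrix.mtx")

    with _open_maybe_gz(directory, ("features.tsv", "features.tsv.gz",
                                    "genes.tsv", "genes.tsv.gz")) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    gene_ids = _dedupe([r[1] if len(r) > 1 else r[0] for r in rows])
    with _open_maybe_gz(directory, ("barcodes.tsv", "barcodes.tsv.gz")) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if counts.shape != (len(gene_ids), len(barcodes)):
        raise ParseError(
            f"matrix shape {counts.shape} does not match {len(gene_ids)} "
            f"features x {len(barcodes)} barcodes"
        )
    return GeneEffectMatrix(counts, gene_ids, barcodes, orientation=GENES_AS_ROWS)


def filter_expression(
    mat: GeneEffectMatrix,
    min_nonzero_cells: int = 50,
    min_genes: int = 100,
    max_genes: int = 4500,
    max_mito_pct: float = 7.0,
    mito_prefix: str = "MT-",
) -> GeneEffectMatrix:
    """Apply the scRNA QC filters.

    Removes genes detected (nonzero) in ``<= min_nonzero_cells`` cells, cells
    with ``<= min_genes`` or ``>= max_genes`` unique detected genes, and cells
    whose percentage of counts mapping to ``mito_prefix`` genes is not below
    ``max_mito_pct``. All masks are computed on the input matrix and applied
    jointly in a single pass.
    """
    g = mat.as_orientation(GENES_AS_ROWS)
    counts = g.values
    nonzero = counts > 0
    gene_keep = nonzero.sum(axis=1) > min_nonzero_cells
    genes_per_cell = nonzero.sum(axis=0)
    cell_keep = (genes_per_cell > min_genes) & (genes_per_cell < max_genes)
    mito_rows = np.array([gid.startswith(mito_prefix) for gid in g.gene_ids])
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = 100.0 * np.where(totals > 0, counts[mito_rows].sum(axis=0) / totals, 0.0)
    cell_keep &= mito_pct < max_mito_pct
    out = GeneEffectMatrix(
        counts[np.ix_(gene_keep, cell_keep)],
        [gid for gid, k in zip(g.gene_ids, gene_keep) if k],
        [sid for sid, k in zip(g.sample_ids, cell_keep) if k],
        orientation=GENES_AS_ROWS,
    )
    return out.as_orientation(mat.orientation)


def log_normalize(mat: GeneEffectMatrix, scale_factor: float = 1e4) -> GeneEffectMatrix:
    """Per-cell log-normalization: ``x -> ln(1 + x * scale_factor / T)``.

    ``T`` is the cell's total count. Matches the Seurat ``NormalizeData``
    convention with its default scale factor of 10,000.
    """
    g = mat.as_orientation(GENES_AS_ROWS)
    totals = g.values.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("cells with zero total count cannot be log-normalized")
    out = replace(g, values=np.log1p(g.values * (scale_factor / totals)))
    return out.as_orientation(mat.orientation)
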