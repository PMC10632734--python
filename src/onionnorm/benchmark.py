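"""Co-annotation benchmarking of similarity networks.

A protein-complex standard (CORUM-like) induces labels on gene pairs: pairs
sharing at least one complex are positives, pairs of standard genes sharing
none are negatives. Ranking all labeled pairs by network weight yields a
precision versus absolute-true-positive curve; per-complex average precision
(one complex's internal pairs as positives, other complexes' internal pairs
as negatives) summarizes how well each complex is recovered. An exclusion
list (mitochondria-like) removes pairs whose *both* members are excluded
genes from the evaluation entirely — they count as neither true nor false
positives; pairs with one or no excluded genes are kept.

Ranking is deterministic: descending weight, then lexicographic gene-pair
id. Per-complex AUPRC is step-interpolated average precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExclusionList


@dataclass
class CoAnnotationStandard:
    """Map of complex id -> gene set; every complex has >= 2 members."""

    complexes: dict[str, set[str]]

    def __post_init__(self) -> None:
        for cid, genes in self.complexes.items():
            if len(genes) < 2:
                raise ValueError(f"complex {cid!r} has fewer than 2 genes")

    @property
    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.complexes.values():
            out |= genes
        return out

    def sizes(self) -> dict[str, int]:
        return {cid: len(genes) for cid, genes in self.complexes.items()}


def read_gmt(path) -> CoAnnotationStandard:
    """Read a GMT standard: complex_id <tab> description <tab> genes..."""
    complexes: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            complexes[parts[0]] = {g for g in parts[2:] if g}
    return CoAnnotationStandard(complexes)


def read_standard_tsv(path) -> CoAnnotationStandard:
    """Read a two-column (complex_id, gene) TSV standard."""
    complexes: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            complexes.setdefault(parts[0], set()).add(parts[1])
    return CoAnnotationStandard(complexes)


def write_gmt(std: CoAnnotationStandard, path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(std.complexes):
            genes = "\t".join(sorted(std.complexes[cid]))
            fh.write(f"{cid}\tna\t{genes}\n")


@dataclass
class PairLabelSet:
    """Unordered labeled gene pairs (keys are ``(a, b)`` with ``a < b``)."""

    positives: set[tuple[str, str]]
    negatives: set[tuple[str, str]]
    excluded: set[tuple[str, str]] = field(default_factory=set)


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def build_pair_labels(
    std: CoAnnotationStandard,
    network_nodes: set[str],
    exclusion: ExclusionList | None = None,
) -> PairLabelSet:
    """Label all pairs of standard genes present among the network nodes."""
    genes = sorted(std.gene_universe & set(network_nodes))
    if not genes:
        raise ValueError("no overlap between standard gene universe and network nodes")
    co = set()
    for members in std.complexes.values():
        inside = sorted(m for m in members if m in network_nodes)
        for i, a in enumerate(inside):
            for b in inside[i + 1:]:
                co.add(_pair(a, b))
    positives, negatives = set(), set()
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            (positives if _pair(a, b) in co else negatives).add(_pair(a, b))
    excluded: set[tuple[str, str]] = set()
    if exclusion is not None and len(exclusion):
        for bucket in (positives, negatives):
            drop = {p for p in bucket if p[0] in exclusion and p[1] in exclusion}
            bucket -= drop
            excluded |= drop
    return PairLabelSet(positives=positives, negatives=negatives, excluded=excluded)


@dataclass
class PrCurve:
    """Precision against cumulative absolute true positives."""

    pairs: list[tuple[str, str]]
    weights: np.ndarray
    is_positive: np.ndarray
    cum_tp: np.ndarray
    precision: np.ndarray
    ties_policy: str = "weight_desc_then_lexicographic"

    @property
    def recall(self) -> np.ndarray:
        total = int(self.is_positive.sum())
        return self.cum_tp / total if total else np.zeros_like(self.cum_tp)


def _network_lookup(net) -> tuple[np.ndarray, dict[str, int]]:
    weights = np.asarray(net.weights, dtype=float)
    index = {g: i for i, g in enumerate(net.node_ids)}
    return weights, index


def ranked_pairs(net, labels: PairLabelSet):
    """Labeled, non-excluded pairs sorted by descending weight then pair id."""
    weights, index = _network_lookup(net)
    entries = []
    for pair in labels.positives | labels.negatives:
        a, b = pair
        if a not in index or b not in index:
            raise ValueError(f"labeled pair {pair} not present in network")
        entries.append((pair, weights[index[a], index[b]],
                        pair in labels.positives))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return entries


def pr_curve(net, labels: PairLabelSet) -> PrCurve:
    """Precision/absolute-TP curve over the deterministic ranking."""
    if not labels.positives:
        raise ValueError("no positive pairs to evaluate")
    entries = ranked_pairs(net, labels)
    is_pos = np.array([e[2] for e in entries], dtype=bool)
    cum_tp = np.cumsum(is_pos)
    ranks = np.arange(1, len(entries) + 1)
    return PrCurve(
        pairs=[e[0] for e in entries],
        weights=np.array([e[1] for e in entries]),
        is_positive=is_pos,
        cum_tp=cum_tp,
        precision=cum_tp / ranks,
    )


def diversity_breakdown(
    net,
    labels: PairLabelSet,
    std: CoAnnotationStandard,
    precision_grid: list[float],
    top_n: int = 10,
) -> pd.DataFrame:
    """Complex composition of the TP pairs captured at each precision cutoff.

    For each cutoff the largest ranking prefix whose running precision is
    still >= the cutoff is taken; each TP pair in the prefix contributes
    fractionally (1/m) to each of the m complexes containing it. The
    ``top_n`` complexes by overall contribution keep their ids; the rest are
    aggregated as ``"other"``. Returns a long-format frame with columns
    (cutoff, complex_id, fraction).
    """
    curve = pr_curve(net, labels)
    membership: dict[tuple[str, str], list[str]] = {}
    for cid, genes in std.complexes.items():
        for pair in labels.positives:
            if pair[0] in genes and pair[1] in genes:
                membership.setdefault(pair, []).append(cid)

    def _contrib(prefix_len: int) -> dict[str, float]:
        contrib: dict[str, float] = {}
        for pos in np.flatnonzero(curve.is_positive[:prefix_len]):
            pair = curve.pairs[pos]
            owners = membership.get(pair, [])
            for cid in owners:
                contrib[cid] = contrib.get(cid, 0.0) + 1.0 / len(owners)
        return contrib

    overall = _contrib(len(curve.pairs))
    named = {cid for cid, _ in sorted(overall.items(),
                                      key=lambda kv: (-kv[1], kv[0]))[:top_n]}
    rows = []
    for cutoff in precision_grid:
        attained = np.flatnonzero(curve.precision >= cutoff)
        if attained.size == 0:
            continue
        prefix = int(attained[-1]) + 1
        contrib = _contrib(prefix)
        total = sum(contrib.values())
        if total == 0:
            continue
        merged: dict[str, float] = {}
        for cid, val in contrib.items():
            key = cid if cid in named else "other"
            merged[key] = merged.get(key, 0.0) + val / total
        for cid, frac in sorted(merged.items()):
            rows.append({"cutoff": cutoff, "complex_id": cid, "fraction": frac})
    return pd.DataFrame(rows, columns=["cutoff", "complex_id", "fraction"])


@dataclass
class ComplexAuprcTable:
    auprc: dict[str, float]
    sizes: dict[str, int]


def per_complex_auprc(
    net,
    std: CoAnnotationStandard,
    exclusion: ExclusionList | None = None,
) -> ComplexAuprcTable:
    """Average precision per complex.

    For each complex, positives are its within-complex pairs present in the
    network and negatives are the within-complex pairs of *other* complexes;
    the ranking is restricted to this pair set. Excluded pairs (both members
    in the exclusion list) participate on neither side.
    """
    weights, index = _network_lookup(net)
    nodes = set(net.node_ids)

    def _scored_pairs(members: set[str]) -> set[tuple[str, str]]:
        inside = sorted(m for m in members if m in nodes)
        out = set()
        for i, a in enumerate(inside):
            for b in inside[i + 1:]:
                p = _pair(a, b)
                if exclusion is not None and p[0] in exclusion and p[1] in exclusion:
                    continue
                out.add(p)
        return out

    complex_pairs = {cid: _scored_pairs(m) for cid, m in std.complexes.items()}
    all_pairs: set[tuple[str, str]] = set()
    for pairs in complex_pairs.values():
        all_pairs |= pairs

    auprc: dict[str, float] = {}
    sizes = std.sizes()
    for cid, pos in complex_pairs.items():
        if not pos:
            warnings.warn(f"complex {cid!r} has no scored pairs; omitted")
            continue
        neg = all_pairs - pos
        universe = sorted(pos | neg)
        entries = sorted(((p, weights[index[p[0]], index[p[1]]]) for p in universe),
                         key=lambda e: (-e[1], e[0]))
        tp = 0
        ap = 0.0
        for rank, (pair, _w) in enumerate(entries, start=1):
            if pair in pos:
                tp += 1
                ap += tp / rank
        auprc[cid] = ap / len(pos)
    return ComplexAuprcTable(auprc=auprc,
                             sizes={cid: sizes[cid] for cid in auprc})


SIZE_BINS: tuple[tuple[str, int, int], ...] = (
    ("2-3", 2, 3), ("4-5", 4, 5), ("6-9", 6, 9), ("10+", 10, 10**9),
)


def auprc_delta_counts(
    table_norm: ComplexAuprcTable,
    table_raw: ComplexAuprcTable,
    threshold: float,
) -> pd.DataFrame:
    """Count complexes crossing an AUPRC threshold due to normalization.

    "increase": raw < t <= normalized; "decrease": normalized < t <= raw.
    Counts are reported per complex-size bin (2-3, 4-5, 6-9, 10+ genes).
    """
    shared = sorted(set(table_norm.auprc) & set(table_raw.auprc))
    counts = {(b[0], d): 0 for b in SIZE_BINS for d in ("increase", "decrease")}
    for cid in shared:
        raw, norm = table_raw.auprc[cid], table_norm.auprc[cid]
        if raw < threshold <= norm:
            direction = "increase"
        elif norm < threshold <= raw:
            direction = "decrease"
        else:
            continue
        size = table_norm.sizes[cid]
        for name, lo, hi in SIZE_BINS:
            if lo <= size <= hi:
                counts[(name, direction)] += 1
                break
    rows = [{"size_bin": name, "direction": d, "count": counts[(name, d)]}
            for name, _, _ in SIZE_BINS for d in ("increase", "decrease")]
    return pd.DataFrame(rows)
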