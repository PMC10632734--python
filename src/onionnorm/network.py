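"""Top-edge networks, connected-component clusters and summary statistics."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import ExclusionList


@dataclass
class EdgeNetwork:
    """Top-N undirected edges, sorted by descending weight."""

    edges: list[tuple[str, str, float]]
    nodes: list[str]
    n_requested: int


def _upper_triangle_entries(net):
    w = np.asarray(net.weights, dtype=float)
    iu, ju = np.triu_indices(w.shape[0], k=1)
    return iu, ju, w[iu, ju]


def top_edges(net, n: int) -> EdgeNetwork:
    """The n highest-weight unordered pairs (ties broken lexicographically)."""
    if n <= 0:
        raise ValueError("n must be positive")
    iu, ju, vals = _upper_triangle_entries(net)
    if n > vals.size:
        raise ValueError(f"n={n} exceeds {vals.size} unordered pairs")
    ids = net.node_ids
    entries = sorted(
        ((ids[i], ids[j]) if ids[i] < ids[j] else (ids[j], ids[i]), v)
        for i, j, v in zip(iu, ju, vals)
    )
    entries.sort(key=lambda e: (-e[1], e[0]))
    chosen = entries[:n]
    edges = [(a, b, float(v)) for (a, b), v in chosen]
    nodes = sorted({g for a, b, _ in edges for g in (a, b)})
    return EdgeNetwork(edges=edges, nodes=nodes, n_requested=n)


def components_and_stats(edge_net: EdgeNetwork) -> tuple[list[set[str]], dict]:
    """Connected components (clusters) and summary statistics."""
    g = nx.Graph()
    g.add_weighted_edges_from(edge_net.edges)
    clusters = [set(c) for c in nx.connected_components(g)]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    n_nodes = g.number_of_nodes()
    stats = {
        "n_clusters": len(clusters),
        "n_genes": n_nodes,
        "n_edges": g.number_of_edges(),
        "mean_degree": (2.0 * g.number_of_edges() / n_nodes) if n_nodes else 0.0,
    }
    return clusters, stats


def cluster_zscore(cluster: set[str], net) -> float:
    """Standardized mean within-cluster edge weight.

    The mean pairwise weight inside the cluster, z-scored against the mean
    and standard deviation of all off-diagonal weights of the network.
    """
    if len(cluster) < 2:
        raise ValueError("cluster z-score undefined for singletons")
    index = {g: i for i, g in enumerate(net.node_ids)}
    members = sorted(cluster)
    missing = [m for m in members if m not in index]
    if missing:
        raise ValueError(f"cluster genes absent from network: {missing}")
    idx = [index[m] for m in members]
    w = np.asarray(net.weights, dtype=float)
    sub = w[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    within_mean = sub[iu].mean()
    iu_all = np.triu_indices(w.shape[0], k=1)
    off = w[iu_all]
    sd = off.std()
    if sd == 0:
        raise ValueError("degenerate network: zero variance of edge weights")
    return float((within_mean - off.mean()) / sd)


def write_edge_tsv(edge_net: EdgeNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b, w in edge_net.edges:
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def write_graphml(edge_net: EdgeNetwork, path,
                  exclusion: ExclusionList | None = None) -> None:
    """Cytoscape-importable GraphML with an ``in_exclusion_list`` node flag."""
    g = nx.Graph()
    for node in edge_net.nodes:
        g.add_node(node, in_exclusion_list=bool(exclusion and node in exclusion))
    for a, b, w in edge_net.edges:
        g.add_edge(a, b, weight=float(w))
    nx.write_graphml(g, path)
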