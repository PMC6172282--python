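"""Thresholded Pearson co-expression networks and global topology metrics.

A co-expression network is an undirected simple graph whose nodes are gene
symbols and whose edges join gene pairs with Pearson correlation at or above
a threshold.  Genes left without any edge are dropped from the node set:
density, path-length and the enrichment background are all defined over
genes that actually participate in the network.
"""

from __future__ import annotations

import itertools
import logging

import networkx as nx
import numpy as np

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "build_coexpression_network",
    "network_density",
    "average_path_length",
    "export_network",
    "read_network",
]


def build_coexpression_network(
    m: ExpressionMatrix,
    rho_threshold: float,
    mode: str = "positive",
) -> nx.Graph:
    """Build the co-expression graph at a given correlation threshold.

    An edge (g, h) is present iff ``rho(g, h) >= rho_threshold`` (mode
    ``"positive"``) or ``|rho| >= rho_threshold`` (mode ``"absolute"``).
    Zero-variance genes have undefined correlations and produce no edges.
    The correlation is stored on each edge as attribute ``rho``; the
    threshold and mode are stored as graph attributes.
    """
    if mode not in ("positive", "absolute"):
        raise ValueError(f"mode must be 'positive' or 'absolute', got {mode!r}")
    if not 0.0 < rho_threshold <= 1.0:
        raise ValueError(f"rho_threshold must be in (0, 1], got {rho_threshold}")
    values = m.values()
    n_genes, n_samples = values.shape
    if n_samples < 3:
        raise ValueError(f"need at least 3 samples, got {n_samples}")
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")

    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(values)
    if n_genes == 1:
        corr = np.array([[1.0]])
    # constant profiles give NaN rows: comparisons with NaN are False below
    scores = corr if mode == "positive" else np.abs(corr)

    genes = m.gene_ids
    net = nx.Graph(rho_threshold=rho_threshold, mode=mode)
    ii, jj = np.nonzero(np.triu(scores >= rho_threshold, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        net.add_edge(genes[i], genes[j], rho=float(corr[i, j]))
    logger.info(
        "co-expression network at rho>=%.2f (%s): %d/%d genes, %d edges",
        rho_threshold, mode, net.number_of_nodes(), n_genes, net.number_of_edges(),
    )
    return net


def network_density(net: nx.Graph) -> float:
    """Edges scaled by the maximum possible: ``2E / (N (N - 1))``."""
    if net.number_of_nodes() < 2:
        raise ValueError("density requires at least 2 nodes")
    return nx.density(net)


def average_path_length(net: nx.Graph) -> float:
    """Mean shortest-path length over mutually reachable node pairs.

    The constructed networks are typically disconnected; pairs in different
    components are excluded from the mean rather than counted as infinite.
    """
    if net.number_of_edges() < 1:
        raise ValueError("average path length requires at least 1 edge")
    total = 0
    n_pairs = 0
    for comp in nx.connected_components(net):
        if len(comp) < 2:
            continue
        sub = net.subgraph(comp)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())  # self-distance is 0
            n_pairs += len(lengths) - 1
    return total / n_pairs


def export_network(net: nx.Graph, path, format: str = "graphml") -> None:
    """Write the network losslessly (nodes, edges, rho attributes).

    ``graphml`` round-trips all attributes; ``edgelist`` is a whitespace-
    delimited ``gene gene rho`` file (one line per edge).
    """
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edgelist":
        with open(path, "w") as fh:
            for u, v, d in net.edges(data=True):
                fh.write(f"{u} {v} {d.get('rho', 1.0):.10g}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network(path, format: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`export_network`."""
    if format == "graphml":
        net = nx.read_graphml(path)
        # graphml stringifies graph attrs in some toolchains; coerce back
        if "rho_threshold" in net.graph:
            net.graph["rho_threshold"] = float(net.graph["rho_threshold"])
        return net
    if format == "edgelist":
        net = nx.Graph()
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                u, v, rho = parts[0], parts[1], float(parts[2])
                net.add_edge(u, v, rho=rho)
        return net
    raise ValueError(f"unknown format {format!r}")
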