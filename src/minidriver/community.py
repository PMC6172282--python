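"""Community structure: Louvain partitions, rewiring nulls, normalized modularity.

Modularity Q of a partition is the Newman-Girvan score

    Q = sum_c [ e_c / m  -  (d_c / 2m)^2 ]

with ``e_c`` the number of intra-module edges, ``d_c`` the summed degree of
module ``c`` and ``m`` the total edge count (unweighted: the thresholded
graph is analysed topologically).  Because Q grows mechanically with network
size and sparsity, comparisons across networks use a normalized score: the
observed Q is rescaled against the mean Q obtained on degree-preserving
randomly rewired replicates of the same graph,

    shifted:  Q_norm = (Q_obs - mean Q_null) / (1 - mean Q_null)
    ratio:    Q_norm = Q_obs / mean Q_null

``shifted`` is the default; both variants are available.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Partition",
    "ModularityReport",
    "modularity",
    "louvain_partition",
    "rewire_degree_preserving",
    "normalized_modularity",
]


@dataclass
class Partition:
    """Assignment of every network node to exactly one module.

    Module ids are contiguous integers starting at 1, numbered by
    decreasing module size (ties by smallest member gene) so that ids are
    deterministic for a deterministic community list.
    """

    assignment: dict[str, int]

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    @property
    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for mod in self.assignment.values():
            sizes[mod] = sizes.get(mod, 0) + 1
        return sizes

    def members(self, module_id: int) -> set[str]:
        return {g for g, mod in self.assignment.items() if mod == module_id}

    def __len__(self) -> int:
        return len(self.assignment)

    @classmethod
    def from_communities(cls, communities) -> "Partition":
        ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
        assignment = {}
        for i, comm in enumerate(ordered, start=1):
            for node in comm:
                assignment[node] = i
        return cls(assignment)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.assignment), "module": list(self.assignment.values())}
        ).sort_values(["module", "gene"], ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Partition":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "module": int})
        return cls(dict(zip(df["gene"], df["module"])))


@dataclass
class ModularityReport:
    """Observed, null and normalized modularity for one network."""

    Q_observed: float
    Q_null_mean: float
    Q_null_sd: float
    Q_normalized: float
    n_null: int
    n_swaps_per_null: int
    seed: int
    formula: str = "shifted"
    degenerate: bool = field(default=False)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def modularity(net: nx.Graph, partition: Partition) -> float:
    """Newman-Girvan modularity of ``partition`` on the unweighted graph."""
    m = net.number_of_edges()
    if m < 1:
        raise ValueError("modularity requires at least 1 edge")
    assignment = partition.assignment
    missing = [n for n in net.nodes if n not in assignment]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing[:5]}")
    intra: dict[int, int] = {}
    degsum: dict[int, int] = {}
    for u, v in net.edges:
        if assignment[u] == assignment[v]:
            intra[assignment[u]] = intra.get(assignment[u], 0) + 1
    for node, deg in net.degree:
        c = assignment[node]
        degsum[c] = degsum.get(c, 0) + deg
    return sum(
        intra.get(c, 0) / m - (degsum[c] / (2.0 * m)) ** 2 for c in degsum
    )


def louvain_partition(net: nx.Graph, seed: int) -> Partition:
    """Louvain greedy modularity optimisation (two-phase, seeded).

    Deterministic for a fixed seed; the returned partition never scores
    below the all-singletons partition.
    """
    if net.number_of_edges() < 1:
        raise ValueError("Louvain requires at least 1 edge")
    communities = nx.community.louvain_communities(net, weight=None, seed=int(seed))
    return Partition.from_communities(communities)


def rewire_degree_preserving(net: nx.Graph, n_swaps: int, seed: int) -> nx.Graph:
    """Randomise edges by ``n_swaps`` attempted double-edge swaps.

    Each attempt picks two distinct edges (a,b), (c,d) and proposes the
    replacement (a,d), (c,b); proposals creating self-loops or multi-edges
    are rejected, so the degree of every node — and hence the degree
    distribution — is exactly preserved.  Graphs admitting no valid swap
    (e.g. a triangle or a star) are returned unchanged.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    rng = random.Random(int(seed))
    null = nx.Graph()
    null.graph.update(net.graph)
    null.add_nodes_from(net.nodes)
    edges = [tuple(e) for e in net.edges]
    null.add_edges_from(edges)
    n_edges = len(edges)
    if n_edges < 2:
        return null
    index = {frozenset(e): i for i, e in enumerate(edges)}
    for _ in range(n_swaps):
        i, j = rng.randrange(n_edges), rng.randrange(n_edges)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        if null.has_edge(a, d) or null.has_edge(c, b):
            continue
        null.remove_edge(a, b)
        null.remove_edge(c, d)
        null.add_edge(a, d)
        null.add_edge(c, b)
        del index[frozenset((a, b))], index[frozenset((c, d))]
        edges[i] = (a, d)
        edges[j] = (c, b)
        index[frozenset((a, d))] = i
        index[frozenset((c, b))] = j
    return null


def normalized_modularity(
    net: nx.Graph,
    n_null: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
    formula: str = "shifted",
) -> ModularityReport:
    """Louvain modularity normalized against a degree-preserving null ensemble.

    Each of the ``n_null`` replicates rewires the graph with
    ``swaps_per_edge * E`` attempted double-edge swaps and re-runs Louvain.
    If the normalisation denominator degenerates (mean null Q of 1 for
    ``shifted``, 0 for ``ratio``) the result is NaN and flagged.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if formula not in ("shifted", "ratio"):
        raise ValueError(f"formula must be 'shifted' or 'ratio', got {formula!r}")
    q_obs = modularity(net, louvain_partition(net, seed=seed))
    n_swaps = swaps_per_edge * net.number_of_edges()
    child_seeds = (
        np.random.SeedSequence(int(seed)).generate_state(2 * n_null) % (2**31)
    )
    q_null = np.empty(n_null)
    for i in range(n_null):
        null = rewire_degree_preserving(net, n_swaps, seed=int(child_seeds[2 * i]))
        q_null[i] = modularity(
            null, louvain_partition(null, seed=int(child_seeds[2 * i + 1]))
        )
    mean_null = float(q_null.mean())
    sd_null = float(q_null.std(ddof=1)) if n_null > 1 else 0.0
    degenerate = False
    if formula == "shifted":
        if np.isclose(mean_null, 1.0):
            q_norm, degenerate = float("nan"), True
        else:
            q_norm = (q_obs - mean_null) / (1.0 - mean_null)
    else:
        if np.isclose(mean_null, 0.0):
            q_norm, degenerate = float("nan"), True
        else:
            q_norm = q_obs / mean_null
    return ModularityReport(
        Q_observed=q_obs,
        Q_null_mean=mean_null,
        Q_null_sd=sd_null,
        Q_normalized=float(q_norm),
        n_null=n_null,
        n_swaps_per_null=n_swaps,
        seed=int(seed),
        formula=formula,
        degenerate=degenerate,
    )
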