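"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive (direct enumeration, BFS by hand,
closed-form combinatorics) and shares no code with the package.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations


def brute_modularity(edges, degrees, assignment) -> float:
    """Newman-Girvan Q by direct edge/degree enumeration."""
    m = len(edges)
    modules = set(assignment.values())
    q = 0.0
    for c in modules:
        e_c = sum(1 for u, v in edges if assignment[u] == c and assignment[v] == c)
        d_c = sum(d for node, d in degrees.items() if assignment[node] == c)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


def brute_density(n_nodes: int, n_edges: int) -> float:
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def bfs_distances(adjacency: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        for nb in adjacency[node]:
            if nb not in dist:
                dist[nb] = dist[node] + 1
                queue.append(nb)
    return dist


def brute_average_path_length(adjacency: dict) -> float:
    """Mean shortest path over mutually reachable ordered pairs."""
    total, n_pairs = 0, 0
    for source in adjacency:
        dist = bfs_distances(adjacency, source)
        for target, d in dist.items():
            if target != source:
                total += d
                n_pairs += 1
    return total / n_pairs


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by exhaustive summation."""
    denom = math.comb(N, n)
    upper = min(K, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x) for x in range(k, upper + 1)
    ) / denom


def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [partition[i] + [first]] + partition[i + 1:]
        yield partition + [[first]]


def exhaustive_best_modularity(edges, nodes) -> float:
    """Maximum Q over every partition of <= ~10 nodes."""
    degrees = {v: 0 for v in nodes}
    for u, v in edges:
        degrees[u] += 1
        degrees[v] += 1
    best = -1.0
    for partition in set_partitions(list(nodes)):
        assignment = {}
        for i, block in enumerate(partition):
            for node in block:
                assignment[node] = i
        best = max(best, brute_modularity(edges, degrees, assignment))
    return best


def km_product_limit(times, events):
    """Hand product-limit estimate: returns {event time: S(t)}."""
    at_risk = len(times)
    surv = 1.0
    out = {}
    order = sorted(set(t for t, e in zip(times, events) if e))
    for t in order:
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei)
        n = sum(1 for ti in times if ti >= t)
        surv *= 1.0 - d / n
        out[t] = surv
    return out
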