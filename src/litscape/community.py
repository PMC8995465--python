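"""Louvain modularity clustering for weighted undirected graphs.

The quality function is Newman–Girvan weighted modularity

    Q = sum_c [ W_c / m  -  resolution * (d_c / 2m)^2 ],

with W_c the total edge weight inside community c, d_c the summed weighted
degree of its nodes and m the total edge weight of the graph.  Louvain
greedily maximises Q in two alternating phases: local moves (each node is
moved to the neighbouring community with the largest positive gain, visit
order shuffled by the seed) until no move helps, then aggregation of
communities into super-nodes, repeated until the partition is stable.  An
exhaustive search over set partitions is provided as an oracle for small
graphs.
"""

from __future__ import annotations

import itertools
import random
from typing import Iterator, Optional

import networkx as nx

__all__ = [
    "modularity",
    "louvain",
    "brute_force_best_partition",
    "partition_to_communities",
]

Partition = dict


def _check_graph(graph: nx.Graph) -> float:
    m = graph.size(weight="weight")
    if m <= 0:
        raise ValueError("modularity undefined for a graph with zero total weight")
    return float(m)


def modularity(
    graph: nx.Graph, partition: Partition, resolution: float = 1.0
) -> float:
    """Weighted modularity of a node -> community mapping.

    Self-loops follow the usual convention: their weight counts once in m and
    in W_c, twice in the node degree.  Raises if a node is missing from the
    partition or the graph has zero total weight.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    missing = [n for n in graph.nodes if n not in partition]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing[:5]}")
    m = _check_graph(graph)
    intra: dict = {}
    deg: dict = {}
    for node, d in graph.degree(weight="weight"):
        c = partition[node]
        deg[c] = deg.get(c, 0.0) + d
    for u, v, w in graph.edges(data="weight", default=1.0):
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0.0) + w
    q = 0.0
    for c in deg:
        q += intra.get(c, 0.0) / m - resolution * (deg[c] / (2.0 * m)) ** 2
    return q


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------

def _one_level(
    adj: dict, loops: dict, m: float, resolution: float, rng: random.Random
) -> dict:
    """Local-moving phase on an adjacency map; returns node -> community."""
    nodes = sorted(adj)
    community = {n: i for i, n in enumerate(nodes)}
    degree = {
        n: sum(adj[n].values()) + 2.0 * loops.get(n, 0.0) for n in nodes
    }
    sigma_tot = {community[n]: degree[n] for n in nodes}
    improved = True
    while improved:
        improved = False
        order = nodes[:]
        rng.shuffle(order)
        for node in order:
            c_old = community[node]
            # weights from node to each neighbouring community
            w_to: dict = {}
            for nbr, w in adj[node].items():
                w_to[community[nbr]] = w_to.get(community[nbr], 0.0) + w
            sigma_tot[c_old] -= degree[node]
            best_c, best_gain = c_old, 0.0
            base = w_to.get(c_old, 0.0) - resolution * degree[node] * sigma_tot[
                c_old
            ] / (2.0 * m)
            for c, w in w_to.items():
                if c == c_old:
                    continue
                gain = (
                    w - resolution * degree[node] * sigma_tot[c] / (2.0 * m)
                ) - base
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            community[node] = best_c
            sigma_tot[best_c] = sigma_tot.get(best_c, 0.0) + degree[node]
            if best_c != c_old:
                improved = True
    return community


def louvain(
    graph: nx.Graph, seed: int = 0, resolution: float = 1.0
) -> Partition:
    """Louvain community detection; deterministic for a given seed.

    Returns a node -> community mapping with contiguous community ids.  The
    achieved modularity never falls below that of the all-singletons
    partition (local moves only ever increase Q); this is asserted at each
    level.  Edgeless graphs return singletons; isolated nodes keep their own
    community.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    nodes = sorted(graph.nodes)
    if graph.size(weight="weight") <= 0:
        return {n: i for i, n in enumerate(nodes)}
    m = float(graph.size(weight="weight"))
    rng = random.Random(seed)

    # adjacency map + self-loop weights, mutable across aggregation levels
    adj: dict = {n: {} for n in nodes}
    loops: dict = {}
    for u, v, w in graph.edges(data="weight", default=1.0):
        if u == v:
            loops[u] = loops.get(u, 0.0) + w
        else:
            adj[u][v] = adj[u].get(v, 0.0) + w
            adj[v][u] = adj[v].get(u, 0.0) + w

    mapping = {n: n for n in nodes}  # original node -> current super-node
    prev_q: Optional[float] = None
    while True:
        level = _one_level(adj, loops, m, resolution, rng)
        q = _partition_quality(adj, loops, level, m, resolution)
        if prev_q is not None and q < prev_q - 1e-9:
            raise AssertionError("modularity decreased across a Louvain level")
        prev_q = q
        # contiguous community ids at this level
        ids: dict = {}
        for n in sorted(level):
            ids.setdefault(level[n], len(ids))
        level = {n: ids[c] for n, c in level.items()}
        if len(set(level.values())) == len(level):
            break
        mapping = {orig: level[cur] for orig, cur in mapping.items()}
        # aggregate
        new_adj: dict = {c: {} for c in set(level.values())}
        new_loops: dict = {}
        for u, nbrs in adj.items():
            cu = level[u]
            for v, w in nbrs.items():
                cv = level[v]
                if cu == cv:
                    new_loops[cu] = new_loops.get(cu, 0.0) + w / 2.0
                else:
                    new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
        for u, w in loops.items():
            cu = level[u]
            new_loops[cu] = new_loops.get(cu, 0.0) + w
        adj, loops = new_adj, new_loops

    final_ids: dict = {}
    for n in sorted(mapping):
        final_ids.setdefault(mapping[n], len(final_ids))
    return {n: final_ids[mapping[n]] for n in mapping}


def _partition_quality(
    adj: dict, loops: dict, partition: dict, m: float, resolution: float
) -> float:
    intra: dict = {}
    deg: dict = {}
    for n, nbrs in adj.items():
        c = partition[n]
        deg[c] = deg.get(c, 0.0) + sum(nbrs.values()) + 2.0 * loops.get(n, 0.0)
        for v, w in nbrs.items():
            if partition[v] == c:
                intra[c] = intra.get(c, 0.0) + w / 2.0
    for n, w in loops.items():
        c = partition[n]
        intra[c] = intra.get(c, 0.0) + w
    return sum(
        intra.get(c, 0.0) / m - resolution * (deg[c] / (2.0 * m)) ** 2
        for c in deg
    )


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

def _set_partitions(items: list) -> Iterator[list[list]]:
    """All set partitions via restricted growth strings."""
    n = len(items)
    if n == 0:
        yield []
        return
    rgs = [0] * n
    while True:
        groups: dict = {}
        for item, g in zip(items, rgs):
            groups.setdefault(g, []).append(item)
        yield list(groups.values())
        # rightmost position whose digit may still grow (rgs[i] <= max prefix)
        i = n - 1
        while i > 0 and rgs[i] > max(rgs[:i]):
            i -= 1
        if i == 0:
            return
        rgs[i] += 1
        for j in range(i + 1, n):
            rgs[j] = 0


def brute_force_best_partition(
    graph: nx.Graph, n_max: int = 10, resolution: float = 1.0
) -> tuple[Partition, float]:
    """Global modularity maximum by exhaustive search (tiny graphs only)."""
    nodes = sorted(graph.nodes)
    if len(nodes) > n_max:
        raise ValueError(f"graph has {len(nodes)} nodes > n_max={n_max}")
    if len(nodes) == 1:
        return {nodes[0]: 0}, 0.0
    _check_graph(graph)
    best_q = -float("inf")
    best: Partition = {}
    for groups in _set_partitions(nodes):
        partition = {n: i for i, grp in enumerate(groups) for n in grp}
        q = modularity(graph, partition, resolution=resolution)
        if q > best_q:
            best_q, best = q, partition
    return best, best_q


def partition_to_communities(partition: Partition) -> list[list]:
    """Invert node -> community into sorted member lists."""
    groups: dict = {}
    for n, c in partition.items():
        groups.setdefault(c, []).append(n)
    return [sorted(groups[c]) for c in sorted(groups)]
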