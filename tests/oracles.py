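"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — hand-rolled BFS, explicit
shortest-path enumeration, exhaustive subset search, full permutation
enumeration — so that it shares no code path with the implementations it
checks.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def count_shortest_paths(adj: dict, dist: dict, source, target,
                         through=None) -> int:
    """Number of shortest source->target paths (optionally via ``through``
    as an interior node), by explicit recursive enumeration."""
    if target not in dist:
        return 0

    def walk(u, seen_through):
        if u == target:
            return 1 if (through is None or seen_through) else 0
        total = 0
        for w in adj[u]:
            if dist.get(w) == dist[u] + 1:
                total += walk(w, seen_through or (w == through and w != target))
        return total

    return walk(source, False)


def brute_centralities(nodes: list, edges: list) -> dict:
    """degree/asp/bc/cco/cc per node for a simple undirected graph.

    bc normalized by (N-1)(N-2)/2; cc = 1 / sum of distances; asp = mean
    distance to reachable nodes (None if isolated in its component).
    """
    adj = {u: set() for u in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    n = len(nodes)
    out = {}
    dists = {u: bfs_distances(adj, u) for u in nodes}
    for v in nodes:
        reach = {u: d for u, d in dists[v].items() if u != v}
        deg = len(adj[v])
        asp = sum(reach.values()) / len(reach) if reach else None
        cc = 1.0 / sum(reach.values()) if reach else 0.0
        k = deg
        if k >= 2:
            nbr_edges = sum(1 for a, b in itertools.combinations(adj[v], 2)
                            if b in adj[a])
            cco = 2.0 * nbr_edges / (k * (k - 1))
        else:
            cco = 0.0
        bc = 0.0
        if n >= 3:
            for b, c in itertools.combinations(nodes, 2):
                if v in (b, c):
                    continue
                sigma = count_shortest_paths(adj, dists[b], b, c)
                if sigma == 0:
                    continue
                via = count_shortest_paths(adj, dists[b], b, c, through=v)
                bc += via / sigma
            bc /= (n - 1) * (n - 2) / 2.0
        out[v] = {"degree": deg, "asp": asp, "bc": bc, "cco": cco, "cc": cc}
    return out


def max_independent_set_size(nodes: list, edges: list) -> int:
    """Exhaustive search over all subsets (independent of the bitmask
    solver inside the package)."""
    nodes = list(nodes)
    edge_set = {frozenset(e) for e in edges}
    best = 0
    for r in range(len(nodes), best, -1):
        for subset in itertools.combinations(nodes, r):
            ok = all(frozenset((a, b)) not in edge_set
                     for a, b in itertools.combinations(subset, 2))
            if ok:
                return r
    return best


def mwu_permutation_p(a: list, b: list) -> float:
    """Exact two-tailed Mann-Whitney p by full enumeration of group
    assignments (tie-free data assumed)."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_stat(sample_a, sample_b):
        return sum(1 for x in sample_a for y in sample_b if x > y)

    observed = u_stat(a, b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), na):
        sa = [pooled[i] for i in idx]
        sb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(sa, sb))
    total = len(us)
    p_le = sum(1 for u in us if u <= observed) / total
    p_ge = sum(1 for u in us if u >= observed) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def hypergeom_tail_ge(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by direct summation."""
    def pmf(x):
        return (math.comb(big_k, x) * math.comb(big_n - big_k, n - x)
                / math.comb(big_n, n))

    return sum(pmf(x) for x in range(k, min(big_k, n) + 1))
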