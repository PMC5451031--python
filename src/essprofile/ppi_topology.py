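"""Per-node PPI network topology scores.

Nine metrics per protein node of a cleaned (simple, undirected) interaction
graph: degree, average shortest path length (ASP), betweenness centrality
normalized to [0,1] by (N-1)(N-2)/2, clustering coefficient, closeness as
the literal reciprocal-of-distance-sum 1/sum d(v,b) (with the conventional
(n-1)/sum d variant exposed), BottleNeck (BN), edge percolation component
(EPC), maximum neighbourhood component (MNC) and its density-style score
DMNC = E_M / N^1.7.

Shortest-path sums are restricted to each node's connected component;
isolated nodes score 0 for betweenness, clustering and closeness, and their
ASP is reported as missing (NaN).

BN builds one deterministic BFS shortest-path tree per root (parent = the
lexicographically smallest neighbour one level up); a node b scores 1 for
root r when at least n_r/4 nodes of the tree (excluding b itself) route to
r through b, with n_r the number of nodes in that tree.

EPC is a seeded Monte Carlo: each replicate keeps every edge independently
with a retention probability, and EPC(v) is the mean number of nodes still
connected to v across replicates.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CleanReport",
    "EPCConfig",
    "clean_graph",
    "read_edge_list",
    "degree",
    "asp",
    "betweenness",
    "clustering_coefficient",
    "closeness",
    "bottleneck",
    "epc",
    "epc_all",
    "mnc",
    "dmnc",
    "node_metrics_table",
]


@dataclass(frozen=True)
class CleanReport:
    self_loops_removed: int
    duplicate_edges_removed: int


@dataclass(frozen=True)
class EPCConfig:
    repetitions: int = 100
    edge_retention_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not 0.0 <= self.edge_retention_probability <= 1.0:
            raise ValueError("edge_retention_probability must be in [0, 1]")


def clean_graph(edges, nodes=None) -> tuple[nx.Graph, CleanReport]:
    """Canonical simple undirected graph from a raw pair list.

    Removes self-loops and duplicate (including reversed) edges, reporting
    how many were dropped.  ``nodes`` optionally adds isolated nodes.
    """
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    loops = dups = 0
    for pair in edges:
        try:
            a, b = pair
        except (TypeError, ValueError):
            raise ValueError(f"malformed edge entry: {pair!r}") from None
        if a == b:
            loops += 1
            g.add_node(a)
            continue
        if g.has_edge(a, b):
            dups += 1
            continue
        g.add_edge(a, b)
    return g, CleanReport(loops, dups)


def read_edge_list(path) -> tuple[nx.Graph, CleanReport]:
    """Two-column tab-separated or SIF (a <rel> b) edge list."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().split("\t")[:2] == ["id_a", "id_b"]:
                continue  # header row of the cohort edge table
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 2:
                edges.append((parts[0], parts[1]))
            elif len(parts) >= 3:  # SIF: source relation target [target...]
                edges.extend((parts[0], t) for t in parts[2:])
            else:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
    return clean_graph(edges)


def _check_node(g: nx.Graph, v) -> None:
    if v not in g:
        raise KeyError(f"node {v!r} not in graph")


def degree(g: nx.Graph, v) -> int:
    _check_node(g, v)
    return g.degree(v)


def asp(g: nx.Graph, v) -> float:
    """Mean BFS distance from v to every reachable node; NaN if none."""
    _check_node(g, v)
    lengths = nx.single_source_shortest_path_length(g, v)
    del lengths[v]
    if not lengths:
        return float("nan")
    return sum(lengths.values()) / len(lengths)


def betweenness(g: nx.Graph, v) -> float:
    _check_node(g, v)
    if g.number_of_nodes() < 3:
        return 0.0
    return float(nx.betweenness_centrality(g, normalized=True)[v])


def clustering_coefficient(g: nx.Graph, v) -> float:
    _check_node(g, v)
    return float(nx.clustering(g, v))


def closeness(g: nx.Graph, v, conventional: bool = False) -> float:
    """1 / sum of shortest-path lengths within v's component (0 if isolated).

    ``conventional=True`` returns the textbook (n_reachable)/sum variant
    instead of the literal reciprocal sum.
    """
    _check_node(g, v)
    lengths = nx.single_source_shortest_path_length(g, v)
    del lengths[v]
    total = sum(lengths.values())
    if total == 0:
        return 0.0
    return (len(lengths) / total) if conventional else (1.0 / total)


def _bfs_tree_deterministic(g: nx.Graph, root) -> tuple[dict, dict]:
    """Parent and distance maps of the BFS shortest-path tree, with the
    lexicographically smallest candidate parent at each node."""
    key = str
    dist = {root: 0}
    parent = {root: None}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for w in sorted(g.neighbors(u), key=key):
            if w not in dist:
                dist[w] = dist[u] + 1
                parent[w] = u
                queue.append(w)
            elif dist[w] == dist[u] + 1 and key(u) < key(parent[w]):
                parent[w] = u  # deterministic: smallest candidate parent
    return parent, dist


def bottleneck(g: nx.Graph, v=None):
    """BN score(s): number of roots r for which the node carries >= n_r/4
    of the routes in the deterministic BFS tree T_r.

    With ``v`` given returns that node's score, otherwise a dict for all
    nodes.
    """
    scores = {u: 0 for u in g.nodes}
    for root in g.nodes:
        parent, dist = _bfs_tree_deterministic(g, root)
        n_r = len(parent)
        if n_r < 2:
            continue
        # descendants (excluding self) via child counts propagated upward
        desc = {u: 0 for u in parent}
        for u in sorted(parent, key=lambda u: -dist[u]):
            p = parent[u]
            if p is not None:
                desc[p] += desc[u] + 1
        for u in parent:
            if u is root:
                continue
            if desc[u] >= n_r / 4.0:
                scores[u] += 1
    if v is not None:
        _check_node(g, v)
        return scores[v]
    return scores


def epc_all(g: nx.Graph, cfg: EPCConfig) -> dict:
    """EPC for every node: mean count of still-connected partners across
    seeded edge-percolation replicates."""
    rng = np.random.default_rng(cfg.seed)
    nodes = list(g.nodes)
    edges = list(g.edges)
    totals = {u: 0.0 for u in nodes}
    p = cfg.edge_retention_probability
    for _ in range(cfg.repetitions):
        keep = rng.random(len(edges)) < p if edges else np.array([], bool)
        sub = nx.Graph()
        sub.add_nodes_from(nodes)
        sub.add_edges_from(e for e, k in zip(edges, keep) if k)
        for comp in nx.connected_components(sub):
            size = len(comp)
            for u in comp:
                totals[u] += size - 1
    return {u: t / cfg.repetitions for u, t in totals.items()}


def epc(g: nx.Graph, v, cfg: EPCConfig) -> float:
    _check_node(g, v)
    return epc_all(g, cfg)[v]


def mnc(g: nx.Graph, v) -> int:
    """Size of the largest connected component of the open neighbourhood."""
    _check_node(g, v)
    nbrs = list(g.neighbors(v))
    if not nbrs:
        return 0
    sub = g.subgraph(nbrs)
    return max(len(c) for c in nx.connected_components(sub))


def dmnc(g: nx.Graph, v, exponent: float = 1.7) -> float:
    """E_M / N^1.7 over the largest neighbourhood component; 0 when that
    component has <= 1 node or no edges."""
    _check_node(g, v)
    nbrs = list(g.neighbors(v))
    if not nbrs:
        return 0.0
    sub = g.subgraph(nbrs)
    comp = max(nx.connected_components(sub), key=len)
    if len(comp) <= 1:
        return 0.0
    comp_sub = sub.subgraph(comp)
    e_m = comp_sub.number_of_edges()
    if e_m == 0:
        return 0.0
    return e_m / (len(comp) ** exponent)


def node_metrics_table(g: nx.Graph, epc_config: EPCConfig | None = None
                       ) -> pd.DataFrame:
    """All nine per-node metrics, one row per node."""
    epc_config = epc_config or EPCConfig()
    n = g.number_of_nodes()
    bc_all = (nx.betweenness_centrality(g, normalized=True) if n >= 3
              else {u: 0.0 for u in g.nodes})
    cco_all = nx.clustering(g)
    bn_all = bottleneck(g)
    epc_values = epc_all(g, epc_config)
    rows = []
    for v in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, v)
        del lengths[v]
        total = sum(lengths.values())
        rows.append({
            "node": v,
            "degree": g.degree(v),
            "asp": (total / len(lengths)) if lengths else float("nan"),
            "bc": float(bc_all[v]),
            "cco": float(cco_all[v]),
            "cc": (1.0 / total) if total else 0.0,
            "bn": bn_all[v],
            "epc": epc_values[v],
            "mnc": mnc(g, v),
            "dmnc": dmnc(g, v),
        })
    return pd.DataFrame(rows).set_index("node")
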