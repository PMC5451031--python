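"""Non-redundant dataset construction by sequence-identity culling.

Pairwise percent identity comes from global alignment (BLOSUM62, affine
gaps, open 10 / extend 0.5) with the alignment length — gaps included — as
the denominator, the conservative choice (more edges, stricter culling).
Sequence pairs at or above an identity threshold form a similarity graph,
and culling removes a set of sequences so that the retained set is an
independent set of that graph: components of at most 12 vertices are
solved exactly for the maximum independent set; larger components fall
back to iteratively removing the highest-degree vertex (ties broken by
removing the lexicographically smallest identifier) until edgeless.

Thresholds below 20% identity are not meaningful for this construction
(structural similarity is lost below the twilight zone) and are rejected
by :func:`cull_sequences`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "CullResult",
    "pairwise_identity",
    "build_similarity_graph",
    "cull",
    "cull_sequences",
    "maximum_independent_set_exact",
]

_EXACT_COMPONENT_LIMIT = 12


@dataclass(frozen=True)
class CullResult:
    retained: frozenset
    removed: frozenset
    threshold: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity: 100 * matches / alignment length (gaps included)."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aln = _ALIGNER.align(seq_a.upper(), seq_b.upper())[0]
    a, b = aln[0], aln[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return 100.0 * matches / aln.shape[1]


def build_similarity_graph(sequences: dict[str, str], threshold: float
                           ) -> nx.Graph:
    """All-pairs similarity graph; edge iff identity >= threshold.

    Every input id is present as a node (isolated when nothing matches);
    edges carry the percent identity as the ``identity`` attribute.
    """
    if not 0.0 < threshold <= 100.0:
        raise ValueError("threshold must be in (0, 100]")
    g = nx.Graph(threshold=threshold)
    g.add_nodes_from(sequences)
    for id_a, id_b in itertools.combinations(sorted(sequences), 2):
        ident = pairwise_identity(sequences[id_a], sequences[id_b])
        if ident >= threshold:
            g.add_edge(id_a, id_b, identity=ident)
    return g


def maximum_independent_set_exact(g: nx.Graph) -> set:
    """Exact maximum independent set by bitmask enumeration (small graphs)."""
    nodes = sorted(g.nodes, key=str)
    n = len(nodes)
    if n > 20:
        raise ValueError("exact search limited to 20 nodes")
    index = {u: i for i, u in enumerate(nodes)}
    adj = [0] * n
    for a, b in g.edges:
        adj[index[a]] |= 1 << index[b]
        adj[index[b]] |= 1 << index[a]
    best_mask, best_size = 0, -1
    for mask in range(1 << n):
        size = mask.bit_count()
        if size <= best_size:
            continue
        if all(not (adj[i] & mask) for i in range(n) if mask >> i & 1):
            best_mask, best_size = mask, size
    return {nodes[i] for i in range(n) if best_mask >> i & 1}


def _greedy_cull(component: nx.Graph) -> set:
    """Remove the max-degree vertex (ties: smallest id) until edgeless;
    returns the removed set."""
    h = component.copy()
    removed = set()
    while h.number_of_edges():
        top = max(d for _, d in h.degree)
        victim = min((u for u, d in h.degree if d == top), key=str)
        h.remove_node(victim)
        removed.add(victim)
    return removed


def cull(graph: nx.Graph) -> CullResult:
    """Independent-set culling of a similarity graph.

    Exact (maximum independent set) on components of <= 12 vertices, greedy
    max-degree removal on larger ones.
    """
    retained: set = set()
    removed: set = set()
    for comp_nodes in nx.connected_components(graph):
        comp = graph.subgraph(comp_nodes)
        if comp.number_of_edges() == 0:
            retained |= set(comp_nodes)
        elif len(comp_nodes) <= _EXACT_COMPONENT_LIMIT:
            keep = maximum_independent_set_exact(comp)
            retained |= keep
            removed |= set(comp_nodes) - keep
        else:
            drop = _greedy_cull(comp)
            removed |= drop
            retained |= set(comp_nodes) - drop
    return CullResult(frozenset(retained), frozenset(removed),
                      float(graph.graph.get("threshold", float("nan"))))


def cull_sequences(sequences: dict[str, str], threshold: float) -> CullResult:
    """Build the similarity graph at ``threshold`` percent and cull it.

    Thresholds below 20% are rejected: below the twilight zone, sequence
    identity no longer implies redundancy.
    """
    if threshold < 20.0:
        raise ValueError(
            f"culling threshold {threshold}% is below the 20% floor")
    return cull(build_similarity_graph(sequences, threshold))
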