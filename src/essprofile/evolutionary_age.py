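"""Evolutionary age assignment from duplication-annotated gene trees.

Each gene receives two ages: the most recent duplication (MRD, nearest
ancestor flagged as a duplication) and the duplicate common ancestor (DCA,
farthest duplication ancestor).  A gene with no duplication ancestor falls
back to the singleton common ancestor (SCA) — the root age — for both.
Ages map onto the 16 canonical phylogenetic age groups (Murinae at 25 MYA
through Opisthokonta at 1215 MYA); by default an exact age match is
required so that data errors surface, with optional snapping to the
nearest tabulated age.

Trees are Newick with hot-comment node annotations
``[&age=<MYA>,event=<duplication|speciation>]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

from ._constants import TAXON_AGES, TAXON_BY_AGE
from .stats_compare import ComparisonSpec, compare_categorical

__all__ = [
    "GeneTree",
    "AgeAssignment",
    "parse_gene_tree",
    "assign_ages",
    "age_group_frequencies",
    "taxon_for_age",
    "TAXON_AGES",
]


@dataclass(frozen=True)
class AgeAssignment:
    gene_id: str
    mrd_sca_age: float
    dca_sca_age: float
    mrd_group: str
    dca_group: str
    has_duplication: bool


class GeneTree:
    """A rooted, ultrametrically ordered gene tree with per-internal-node
    (age, event) annotations and gene identifiers at the leaves."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._ann: dict[int, tuple[float, str]] = {}
        self._leaves: dict[str, dendropy.Node] = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                if node.taxon is None:
                    raise ValueError("leaf without a gene identifier")
                self._leaves[node.taxon.label] = node
            else:
                age = node.annotations.get_value("age")
                event = node.annotations.get_value("event")
                if age is None or event is None:
                    raise ValueError(
                        "internal node missing [&age=...,event=...] annotation")
                if event not in ("duplication", "speciation"):
                    raise ValueError(f"unknown event {event!r}")
                self._ann[id(node)] = (float(age), event)
        root = tree.seed_node
        if root.is_leaf() or id(root) not in self._ann:
            raise ValueError("tree must have an annotated internal root")
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node is root:
                continue
            parent_age = self._ann[id(node.parent_node)][0]
            if self._ann[id(node)][0] > parent_age:
                raise ValueError("node ages must be non-increasing from root")

    @property
    def root_age(self) -> float:
        return self._ann[id(self._tree.seed_node)][0]

    @property
    def leaf_ids(self) -> list[str]:
        return list(self._leaves)

    def ancestor_events(self, gene_id: str) -> list[tuple[float, str]]:
        """(age, event) for each internal ancestor, nearest first."""
        if gene_id not in self._leaves:
            raise KeyError(f"leaf {gene_id!r} not present in tree")
        out = []
        node = self._leaves[gene_id].parent_node
        while node is not None:
            out.append(self._ann[id(node)])
            node = node.parent_node
        return out


def parse_gene_tree(newick: str) -> GeneTree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick",
        suppress_internal_node_taxa=True,
        extract_comment_metadata=True,
    )
    return GeneTree(tree)


def taxon_for_age(age: float, snap: bool = False) -> str:
    """Map an age in MYA to its canonical taxon group label."""
    if age in TAXON_BY_AGE:
        return TAXON_BY_AGE[age]
    if snap:
        return min(TAXON_AGES, key=lambda ta: abs(ta[1] - age))[0]
    raise ValueError(
        f"age {age} MYA does not match any of the 16 canonical age groups "
        "(pass snap=True to snap to the nearest)")


def assign_ages(tree: GeneTree, gene_id: str, snap: bool = False) -> AgeAssignment:
    """MRD/DCA ages for one leaf, with SCA (root age) fallback."""
    events = tree.ancestor_events(gene_id)
    dup_ages = [age for age, event in events if event == "duplication"]
    if dup_ages:
        mrd, dca = dup_ages[0], dup_ages[-1]
    else:
        mrd = dca = tree.root_age
    return AgeAssignment(
        gene_id=gene_id,
        mrd_sca_age=mrd,
        dca_sca_age=dca,
        mrd_group=taxon_for_age(mrd, snap=snap),
        dca_group=taxon_for_age(dca, snap=snap),
        has_duplication=bool(dup_ages),
    )


def age_group_frequencies(assignments: list[AgeAssignment],
                          labels: dict[str, str],
                          mode: str = "MRD",
                          m: int = 16,
                          alpha: float = 0.05) -> pd.DataFrame:
    """16-row percentage table per group with per-row chi-squared p-values.

    ``mode`` selects MRD+SCA or DCA+SCA ages.  Percentages per column sum
    to 100 (up to rounding) over the 16 canonical taxon rows.
    """
    if mode not in ("MRD", "DCA"):
        raise ValueError("mode must be 'MRD' or 'DCA'")
    attr = "mrd_group" if mode == "MRD" else "dca_group"
    ess = [a for a in assignments if labels[a.gene_id] == "essential"]
    via = [a for a in assignments if labels[a.gene_id] == "viable"]
    if not ess or not via:
        raise ValueError("both groups must be non-empty")
    n_e, n_v = len(ess), len(via)
    rows = []
    for taxon, age in TAXON_AGES:
        k_e = sum(1 for a in ess if getattr(a, attr) == taxon)
        k_v = sum(1 for a in via if getattr(a, attr) == taxon)
        res = compare_categorical(
            k_e, n_e, k_v, n_v,
            ComparisonSpec(feature=taxon, kind="categorical", m=m, alpha=alpha))
        rows.append({
            "taxon": taxon,
            "age_mya": age,
            "pct_essential": res.summary_a,
            "pct_viable": res.summary_b,
            "test": res.test,
            "statistic": res.statistic,
            "p": res.p,
            "threshold": res.threshold,
            "significant": res.significant,
        })
    return pd.DataFrame(rows).set_index("taxon")
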