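"""Labelled two-group synthetic cohorts for end-to-end pipeline testing.

The generator emulates the group structure of the mouse essentiality
study: an essential and a viable gene set with configurable median shifts
in gene architecture (log-normal lengths, truncated-Poisson transcript and
exon counts, Beta GC), Dirichlet amino-acid compositions with group
shifts, Bernoulli annotation flags, zero-inflated gamma-Poisson EST counts
over the 13 developmental stages, a degree-biased preferential-attachment
PPI graph in which essential nodes attach with a fitness multiplier, and
ultrametric gene trees whose duplication nodes sit at the 16 canonical
phylogenetic ages.  Defaults are the published study contrasts (1301 vs
3451 genes, 28913 vs 21629 bp median gene length, signal-peptide rates
0.164 vs 0.291, and so on).

No attempt is made to simulate real mouse sequence content or real tree
topologies; the cohorts exist so every downstream stage is testable
without database downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import _constants as C
from .expression_tpm import ExpressionTable, read_expression_table, write_expression_table
from .sequence_features import GeneModel, ProteinRecord, TranscriptModel

__all__ = [
    "GroupEffectConfig",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "expression_mean_for_fraction",
    "expressed_fraction_for_mean",
]

_FLAGS = tuple(C.DEFAULT_ANNOTATION_RATES)


def _default_alpha(concentration: float = 300.0) -> dict[str, tuple[float, float]]:
    return {
        aa: (e / 100.0 * concentration, v / 100.0 * concentration)
        for aa, (e, v) in C.DEFAULT_AA_PERCENT.items()
    }


def expression_mean_for_fraction(fraction: float, shape: float = 0.5,
                                 zero_inflation: float = 0.0) -> float:
    """Gamma-Poisson mean whose zero probability realises an expressed
    fraction, given the structural zero-inflation probability."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    reachable = 1.0 - zero_inflation
    if fraction >= reachable:
        raise ValueError("fraction unreachable under this zero inflation")
    p_zero = 1.0 - fraction / reachable  # conditional Poisson-zero prob
    if p_zero <= 0.0:
        raise ValueError("fraction unreachable")
    return shape * (p_zero ** (-1.0 / shape) - 1.0)


def expressed_fraction_for_mean(mean: float, shape: float = 0.5,
                                zero_inflation: float = 0.0) -> float:
    p_zero = (1.0 + mean / shape) ** (-shape)
    return (1.0 - zero_inflation) * (1.0 - p_zero)


def _default_expression_mean() -> dict[str, tuple[float, float]]:
    return {
        stage: (expression_mean_for_fraction(fe), expression_mean_for_fraction(fv))
        for stage, (fe, fv) in C.DEFAULT_EXPRESSED_FRACTION.items()
    }


@dataclass(frozen=True)
class GroupEffectConfig:
    """All generator knobs; tuples are (essential, viable)."""

    n_essential: int = 1301
    n_viable: int = 3451
    gene_length_median: tuple[float, float] = C.DEFAULT_GENE_LENGTH_MEDIAN
    exon_total_median: tuple[float, float] = C.DEFAULT_EXON_TOTAL_MEDIAN
    exon_count_mean: tuple[float, float] = C.DEFAULT_EXON_COUNT_MEAN
    transcript_count_mean: tuple[float, float] = C.DEFAULT_TRANSCRIPT_COUNT_MEAN
    gc_mean: tuple[float, float] = C.DEFAULT_GC_MEAN
    gene_length_sigma: float = 0.8
    exon_total_sigma: float = 0.5
    gc_concentration: float = 150.0
    aa_dirichlet_alpha: dict[str, tuple[float, float]] = field(
        default_factory=_default_alpha)
    annotation_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(C.DEFAULT_ANNOTATION_RATES))
    tm_rate: tuple[float, float] = C.DEFAULT_TM_RATE
    enzyme_probs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(C.DEFAULT_ENZYME_PROBS))
    expression_mean: dict[str, tuple[float, float]] = field(
        default_factory=_default_expression_mean)
    zero_inflation: tuple[float, float] = (0.0, 0.0)
    nb_shape: float = 0.5
    ppi_fitness_multiplier: float = 2.0
    ppi_edges_per_node: int = 3
    tree_duplication_age_weights: dict[float, tuple[float, float]] = field(
        default_factory=lambda: dict(C.DEFAULT_AGE_WEIGHTS))
    duplication_probability: float = 0.6
    paralog_probability: float = 0.15
    paralog_mutation_rate: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_essential < 0 or self.n_viable < 0:
            raise ValueError("n_essential/n_viable: counts must be >= 0")
        for name in ("gene_length_median", "exon_total_median"):
            if any(x <= 0 for x in getattr(self, name)):
                raise ValueError(f"{name}: medians must be > 0")
        for name in ("exon_count_mean", "transcript_count_mean"):
            if any(x < 1 for x in getattr(self, name)):
                raise ValueError(f"{name}: means must be >= 1")
        if any(not 0 < x < 1 for x in self.gc_mean):
            raise ValueError("gc_mean: fractions must be in (0, 1)")
        for aa, pair in self.aa_dirichlet_alpha.items():
            if any(a <= 0 for a in pair):
                raise ValueError(f"aa_dirichlet_alpha[{aa!r}]: entries must be > 0")
        for flag, pair in self.annotation_rates.items():
            if any(not 0 <= r <= 1 for r in pair):
                raise ValueError(f"annotation_rates[{flag!r}]: rates must be in [0, 1]")
        if any(not 0 <= r <= 1 for r in self.tm_rate):
            raise ValueError("tm_rate: rates must be in [0, 1]")
        for grp in (0, 1):
            total = sum(p[grp] for p in self.enzyme_probs.values())
            if total > 1.0:
                raise ValueError("enzyme_probs: group probabilities exceed 1")
        for stage, pair in self.expression_mean.items():
            if stage not in C.DEVELOPMENTAL_STAGES:
                raise ValueError(f"expression_mean: unknown stage {stage!r}")
            if any(x < 0 for x in pair):
                raise ValueError(f"expression_mean[{stage!r}]: means must be >= 0")
        if set(self.expression_mean) != set(C.DEVELOPMENTAL_STAGES):
            raise ValueError("expression_mean: all 13 stages required")
        if any(not 0 <= z <= 1 for z in self.zero_inflation):
            raise ValueError("zero_inflation: probabilities must be in [0, 1]")
        if self.ppi_fitness_multiplier < 1.0:
            raise ValueError("ppi_fitness_multiplier: must be >= 1")
        if self.ppi_edges_per_node < 0:
            raise ValueError("ppi_edges_per_node: must be >= 0")
        ages = set(self.tree_duplication_age_weights)
        if ages != set(C.TAXON_BY_AGE):
            raise ValueError("tree_duplication_age_weights: must cover the 16 ages")
        for grp in (0, 1):
            if sum(w[grp] for w in self.tree_duplication_age_weights.values()) <= 0:
                raise ValueError("tree_duplication_age_weights: group weights sum to 0")
        if not 0 <= self.duplication_probability <= 1:
            raise ValueError("duplication_probability: must be in [0, 1]")
        if not 0 <= self.paralog_probability <= 1:
            raise ValueError("paralog_probability: must be in [0, 1]")

    @classmethod
    def null(cls, n_per_group: int = 100, seed: int = 0, **overrides
             ) -> "GroupEffectConfig":
        """Both groups identical: the no-effect calibration condition.

        Uses compact gene sizes so repeated simulation is cheap; every
        group contrast collapses to its midpoint.
        """
        mid_rates = {f: (0.3, 0.3) for f in C.DEFAULT_ANNOTATION_RATES}
        mid_expr = {s: (expression_mean_for_fraction(0.5),) * 2
                    for s in C.DEVELOPMENTAL_STAGES}
        weights = {age: (w[1], w[1])
                   for age, w in C.DEFAULT_AGE_WEIGHTS.items()}
        alpha = {aa: (a[1], a[1]) for aa, a in _default_alpha().items()}
        enz = {k: (p[1], p[1]) for k, p in C.DEFAULT_ENZYME_PROBS.items()}
        base = dict(
            n_essential=n_per_group, n_viable=n_per_group,
            gene_length_median=(5000.0, 5000.0),
            exon_total_median=(900.0, 900.0),
            exon_count_mean=(6.0, 6.0),
            transcript_count_mean=(3.0, 3.0),
            gc_mean=(0.46, 0.46),
            aa_dirichlet_alpha=alpha,
            annotation_rates=mid_rates,
            tm_rate=(0.25, 0.25),
            enzyme_probs=enz,
            expression_mean=mid_expr,
            ppi_fitness_multiplier=1.0,
            tree_duplication_age_weights=weights,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)

    def with_seed(self, seed: int) -> "GroupEffectConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticCohort:
    genes: list[GeneModel]
    proteins: list[ProteinRecord]
    expression: ExpressionTable
    ppi: nx.Graph
    trees: dict[str, str]  # gene id -> annotated newick
    labels: dict[str, str]

    def __post_init__(self) -> None:
        gene_ids = [g.gene_id for g in self.genes]
        if set(gene_ids) != set(self.labels):
            raise ValueError("every gene must have exactly one label")
        if [p.protein_id for p in self.proteins] != gene_ids:
            raise ValueError("protein ids must map 1-1 to gene ids")

    def equals(self, other: "SyntheticCohort") -> bool:
        return (
            self.genes == other.genes
            and self.proteins == other.proteins
            and self.expression.est_counts.equals(other.expression.est_counts)
            and set(self.ppi.nodes) == set(other.ppi.nodes)
            and {frozenset(e) for e in self.ppi.edges}
            == {frozenset(e) for e in other.ppi.edges}
            and self.trees == other.trees
            and self.labels == other.labels
        )


def _fmt_age(age: float) -> str:
    return f"{age:g}"


def _gene_tree_newick(gene_id: str, mrd: float, dca: float | None,
                      mid: float | None) -> str:
    """Ultrametric newick with [&age=...,event=...] annotations."""
    if dca is None:  # singleton: speciation root only
        a = _fmt_age(mrd)
        return (f"({gene_id}:{a},{gene_id}_o1:{a})"
                f"[&age={a},event=speciation];")
    m, d = _fmt_age(mrd), _fmt_age(dca)
    inner = f"({gene_id}:{m},{gene_id}_p1:{m})[&age={m},event=duplication]"
    if dca == mrd:
        return inner + ";"
    if mid is not None:
        x = _fmt_age(mid)
        sp = (f"({inner}:{_fmt_age(mid - mrd)},{gene_id}_o1:{x})"
              f"[&age={x},event=speciation]")
        return (f"({sp}:{_fmt_age(dca - mid)},{gene_id}_o2:{d})"
                f"[&age={d},event=duplication];")
    return (f"({inner}:{_fmt_age(dca - mrd)},{gene_id}_o1:{d})"
            f"[&age={d},event=duplication];")


def generate_cohort(config: GroupEffectConfig) -> SyntheticCohort:
    """Deterministic (seeded) two-group cohort under ``config``."""
    rng = np.random.default_rng(config.seed)
    aa_letters = np.array(list(C.STANDARD_AA))
    alpha = np.array([config.aa_dirichlet_alpha[aa] for aa in C.STANDARD_AA])

    genes: list[GeneModel] = []
    proteins: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    trees: dict[str, str] = {}
    est_rows: list[np.ndarray] = []
    seq_pool: dict[int, list[str]] = {0: [], 1: []}

    ages = np.array(sorted(config.tree_duplication_age_weights))
    age_w = np.array([config.tree_duplication_age_weights[a] for a in ages])

    stage_means = np.array([config.expression_mean[s]
                            for s in C.DEVELOPMENTAL_STAGES])  # 13 x 2

    for grp, n, prefix in ((0, config.n_essential, "ess"),
                           (1, config.n_viable, "via")):
        if n == 0:
            continue
        w = age_w[:, grp] / age_w[:, grp].sum()
        for i in range(n):
            gid = f"{prefix}{i + 1:05d}"
            labels[gid] = C.GROUPS[grp]

            # --- gene architecture ---------------------------------------
            n_tx = 1 + rng.poisson(config.transcript_count_mean[grp] - 1.0)
            exon_total = rng.lognormal(
                math.log(config.exon_total_median[grp]), config.exon_total_sigma)
            gene_length = rng.lognormal(
                math.log(config.gene_length_median[grp]), config.gene_length_sigma)
            exon_total = int(max(90, min(exon_total, 0.9 * gene_length)))
            gene_length = int(max(gene_length, exon_total))
            tx_models = []
            principal_exons = 1 + rng.poisson(config.exon_count_mean[grp] - 1.0)
            for t in range(n_tx):
                if t == 0:
                    n_ex, total = principal_exons, exon_total
                else:
                    n_ex = 1 + rng.poisson(config.exon_count_mean[grp] - 1.0)
                    total = int(exon_total * rng.uniform(0.3, 0.999))
                n_ex = min(n_ex, max(1, total))
                # exact split: each exon >= 1 bp, sums to the transcript total
                lens = rng.multinomial(total - n_ex,
                                       rng.dirichlet(np.full(n_ex, 2.0))) + 1
                tx_models.append(TranscriptModel(tuple(int(x) for x in lens)))
            gc_k = config.gc_concentration
            gc = float(rng.beta(config.gc_mean[grp] * gc_k,
                                (1.0 - config.gc_mean[grp]) * gc_k))
            genes.append(GeneModel(gid, gene_length, gc, tuple(tx_models)))

            # --- protein sequence + annotations --------------------------
            length = max(30, exon_total // 3)
            pool = seq_pool[grp]
            if pool and rng.random() < config.paralog_probability:
                template = pool[rng.integers(len(pool))]
                seq_arr = np.array(list(template))
                mut = rng.random(seq_arr.size) < config.paralog_mutation_rate
                seq_arr[mut] = aa_letters[rng.integers(0, 20, mut.sum())]
                seq = "".join(seq_arr)
            else:
                comp = rng.dirichlet(alpha[:, grp])
                seq = "".join(aa_letters[rng.choice(20, size=length, p=comp)])
            pool.append(seq)
            flags = {f: bool(rng.random() < config.annotation_rates[f][grp])
                     for f in config.annotation_rates}
            enz_names = list(config.enzyme_probs)
            enz_p = np.array([config.enzyme_probs[k][grp] for k in enz_names])
            u = rng.random()
            enzyme = None
            acc = 0.0
            for name, p in zip(enz_names, enz_p):
                acc += p
                if u < acc:
                    enzyme = name
                    break
            tm = 0
            if rng.random() < config.tm_rate[grp]:
                tm = 1 + int(rng.poisson(1.3))
            proteins.append(ProteinRecord(gid, seq, flags, enzyme, tm))

            # --- expression ----------------------------------------------
            lam = stage_means[:, grp]
            shape = config.nb_shape
            with np.errstate(divide="ignore", invalid="ignore"):
                gam = rng.gamma(shape, np.where(lam > 0, lam / shape, 0.0))
            counts = rng.poisson(gam)
            structural = rng.random(13) < config.zero_inflation[grp]
            counts = np.where(structural | (lam <= 0), 0, counts)
            est_rows.append(counts.astype(int))

            # --- gene tree -----------------------------------------------
            mrd = float(rng.choice(ages, p=w))
            if rng.random() < config.duplication_probability:
                older = ages[ages >= mrd]
                ow = w[ages >= mrd]
                dca = float(rng.choice(older, p=ow / ow.sum()))
                between = ages[(ages > mrd) & (ages < dca)]
                mid = float(rng.choice(between)) if between.size else None
                trees[gid] = _gene_tree_newick(gid, mrd, dca, mid)
            else:
                trees[gid] = _gene_tree_newick(gid, mrd, None, None)

    gene_ids = [g.gene_id for g in genes]
    expression = ExpressionTable(pd.DataFrame(
        np.array(est_rows, dtype=int).reshape(len(gene_ids), 13),
        index=gene_ids, columns=list(C.DEVELOPMENTAL_STAGES)))

    ppi = _preferential_attachment(
        gene_ids, labels, config.ppi_edges_per_node,
        config.ppi_fitness_multiplier, rng)

    return SyntheticCohort(genes, proteins, expression, ppi, trees, labels)


def _preferential_attachment(gene_ids: list[str], labels: dict[str, str],
                             m: int, fitness_multiplier: float,
                             rng: np.random.Generator) -> nx.Graph:
    """Degree x fitness preferential attachment over all genes."""
    g = nx.Graph()
    g.add_nodes_from(gene_ids)
    if len(gene_ids) < 2 or m == 0:
        return g
    order = list(gene_ids)
    rng.shuffle(order)
    fitness = np.array([fitness_multiplier if labels[u] == "essential" else 1.0
                        for u in order])
    deg = np.zeros(len(order))
    for t in range(1, len(order)):
        k = min(m, t)
        w = (deg[:t] + 1.0) * fitness[:t]
        targets = rng.choice(t, size=k, replace=False, p=w / w.sum())
        for j in targets:
            g.add_edge(order[t], order[j])
            deg[t] += 1
            deg[j] += 1
    return g


# ---------------------------------------------------------------------------
# cohort I/O: FASTA + tab-separated tables + newick, lossless round trip
# ---------------------------------------------------------------------------

_MANIFEST = ("proteins.fasta", "gene_models.tsv", "expression.tsv",
             "annotations.tsv", "ppi_edges.tsv", "trees.nwk", "labels.tsv")


def write_cohort(cohort: SyntheticCohort, directory) -> list[Path]:
    """Write the cohort as plain-text artifacts; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with open(directory / "proteins.fasta", "w") as fh:
        for p in cohort.proteins:
            fh.write(f">{p.protein_id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i:i + 60] + "\n")

    with open(directory / "gene_models.tsv", "w") as fh:
        fh.write("gene_id\tgene_length\tgc\ttranscript_exon_lengths\n")
        for g in cohort.genes:
            tx = ";".join(",".join(str(x) for x in t.exon_lengths)
                          for t in g.transcripts)
            fh.write(f"{g.gene_id}\t{g.gene_length}\t{g.gc!r}\t{tx}\n")

    write_expression_table(cohort.expression, directory / "expression.tsv")

    with open(directory / "annotations.tsv", "w") as fh:
        fh.write("protein_id\t" + "\t".join(_FLAGS)
                 + "\tenzyme_class\ttm_count\n")
        for p in cohort.proteins:
            bits = "\t".join(str(int(p.flags.get(f, False))) for f in _FLAGS)
            enz = p.enzyme_class or "-"
            fh.write(f"{p.protein_id}\t{bits}\t{enz}\t{p.tm_count}\n")

    with open(directory / "ppi_edges.tsv", "w") as fh:
        fh.write("id_a\tid_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in cohort.ppi.edges):
            fh.write(f"{a}\t{b}\n")

    with open(directory / "trees.nwk", "w") as fh:
        for gid in sorted(cohort.trees):
            fh.write(f"{gid}\t{cohort.trees[gid]}\n")

    with open(directory / "labels.tsv", "w") as fh:
        fh.write("gene_id\tlabel\n")
        for g in cohort.genes:
            fh.write(f"{g.gene_id}\t{cohort.labels[g.gene_id]}\n")

    return [directory / name for name in _MANIFEST]


def read_cohort(directory) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)

    sequences: dict[str, str] = {}
    current = None
    with open(directory / "proteins.fasta") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                current = line[1:].split()[0]
                sequences[current] = ""
            elif line and current is not None:
                sequences[current] += line

    labels: dict[str, str] = {}
    order: list[str] = []
    with open(directory / "labels.tsv") as fh:
        next(fh)
        for line in fh:
            gid, label = line.rstrip("\n").split("\t")
            labels[gid] = label
            order.append(gid)

    genes: list[GeneModel] = []
    with open(directory / "gene_models.tsv") as fh:
        next(fh)
        for line in fh:
            gid, length, gc, tx = line.rstrip("\n").split("\t")
            transcripts = tuple(
                TranscriptModel(tuple(int(x) for x in part.split(",")))
                for part in tx.split(";"))
            genes.append(GeneModel(gid, int(length), float(gc), transcripts))

    ann = pd.read_csv(directory / "annotations.tsv", sep="\t", index_col=0,
                      keep_default_na=False) if order else pd.DataFrame()
    proteins = []
    for gid in order:
        if order and not ann.empty:
            row = ann.loc[gid]
            flags = {f: bool(int(row[f])) for f in _FLAGS}
            enzyme = None if row["enzyme_class"] == "-" else row["enzyme_class"]
            tm = int(row["tm_count"])
        else:
            flags, enzyme, tm = {}, None, 0
        proteins.append(ProteinRecord(gid, sequences[gid], flags, enzyme, tm))

    expression = read_expression_table(directory / "expression.tsv")

    ppi = nx.Graph()
    ppi.add_nodes_from(order)
    with open(directory / "ppi_edges.tsv") as fh:
        next(fh)
        for line in fh:
            a, b = line.rstrip("\n").split("\t")
            ppi.add_edge(a, b)

    trees: dict[str, str] = {}
    with open(directory / "trees.nwk") as fh:
        for line in fh:
            if line.strip():
                gid, nwk = line.rstrip("\n").split("\t", 1)
                trees[gid] = nwk

    return SyntheticCohort(genes, proteins, expression, ppi, trees, labels)
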