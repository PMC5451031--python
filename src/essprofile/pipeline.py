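"""End-to-end orchestration: generate/load -> extract -> cull -> compare.

One seeded run produces a report bundle of comparison tables mirroring the
study layout: gene features (Bonferroni family m=6), Pepstats protein
features (m=13), 20 amino-acid frequencies (m=20), stage expression
frequencies (m=13), phylogenetic age groups (m=16), PTM/transcription
keywords (m=4), enzyme classes (m=6), subcellular locations (m=12 for the
annotation block), housekeeping/tissue-enriched (m=2), and the PPI metric
comparisons (five centralities m=5, four hub scores m=4).  Comparisons are
re-run independently on each culled dataset requested.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._constants import DEVELOPMENTAL_STAGES, ENZYME_CLASSES, STANDARD_AA
from .evolutionary_age import age_group_frequencies, assign_ages, parse_gene_tree
from .expression_tpm import stage_expression_frequencies, tpm
from .ppi_topology import EPCConfig, node_metrics_table
from .redundancy_culling import cull_sequences
from .sequence_features import gene_feature_table, protein_feature_table
from .stats_compare import ComparisonSpec, TestResult, compare_categorical, compare_numeric
from .synthetic_data import GroupEffectConfig, SyntheticCohort, generate_cohort, read_cohort

log = logging.getLogger("essprofile")

__all__ = ["RunConfig", "ReportBundle", "run", "validate_inputs"]

DEFAULT_FAMILY_SIZES = {
    "gene_features": 6,
    "pepstats": 13,
    "amino_acids": 20,
    "stages": 13,
    "age_groups": 16,
    "keywords": 4,
    "enzyme_class": 6,
    "subcellular": 12,
    "housekeeping": 2,
    "ppi_centralities": 5,
    "ppi_hubs": 4,
}

GENE_FEATURES = ("gene_length", "gc_percent", "n_transcripts", "n_exons",
                 "exon_length", "intron_length")
PEPSTATS_FEATURES = ("length", "mw", "charge", "pi", "tiny", "small",
                     "aliphatic", "aromatic", "non_polar", "polar", "charged",
                     "basic", "acidic")
KEYWORD_FLAGS = ("phosphoprotein", "glycoprotein", "acetylation", "transcription")
LOCATION_FLAGS = ("loc_nucleus", "loc_cytoplasm", "loc_plasma_membrane",
                  "loc_extracellular")
PPI_CENTRALITIES = ("degree", "asp", "bc", "cco", "cc")
PPI_HUBS = ("bn", "epc", "mnc", "dmnc")


@dataclass(frozen=True)
class RunConfig:
    synthetic: GroupEffectConfig | None = None
    input_dir: str | None = None
    culling_thresholds: tuple[float, ...] = ()
    family_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_SIZES))
    epc: EPCConfig = EPCConfig()
    alpha: float = 0.05
    compute_ppi_metrics: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError("exactly one of synthetic/input_dir is required")
        for t in self.culling_thresholds:
            if t < 20.0 or t > 100.0:
                raise ValueError(f"culling threshold {t}% outside [20, 100]")


@dataclass
class ReportBundle:
    """Per-dataset comparison tables plus the run manifest."""

    tables: dict[str, pd.DataFrame]
    manifest: dict

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.tables):
            h.update(name.encode())
            h.update(self.tables[name].round(12).to_csv().encode())
        return h.hexdigest()

    def write(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            path = directory / f"{name}.tsv"
            path.parent.mkdir(parents=True, exist_ok=True)
            table.to_csv(path, sep="\t")
        import json

        with open(directory / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _result_row(res: TestResult) -> dict:
    return {
        "feature": res.feature,
        "essential": res.summary_a,
        "viable": res.summary_b,
        "test": res.test,
        "statistic": res.statistic,
        "p": res.p,
        "threshold": res.threshold,
        "significant": res.significant,
    }


def _numeric_block(table: pd.DataFrame, features, labels, m, alpha) -> pd.DataFrame:
    ess = [i for i in table.index if labels[i] == "essential"]
    via = [i for i in table.index if labels[i] == "viable"]
    rows = []
    for feat in features:
        res = compare_numeric(
            table.loc[ess, feat], table.loc[via, feat],
            ComparisonSpec(feature=feat, kind="numeric", m=m, alpha=alpha))
        rows.append(_result_row(res))
    return pd.DataFrame(rows).set_index("feature")


def _flag_block(proteins, flags, labels, m, alpha) -> pd.DataFrame:
    ess = [p for p in proteins if labels[p.protein_id] == "essential"]
    via = [p for p in proteins if labels[p.protein_id] == "viable"]
    rows = []
    for flag in flags:
        res = compare_categorical(
            sum(p.flags.get(flag, False) for p in ess), len(ess),
            sum(p.flags.get(flag, False) for p in via), len(via),
            ComparisonSpec(feature=flag, kind="categorical", m=m, alpha=alpha))
        rows.append(_result_row(res))
    return pd.DataFrame(rows).set_index("feature")


def _comparison_tables(cohort: SyntheticCohort, cfg: RunConfig,
                       dataset: str, gene_ids: list[str] | None = None
                       ) -> dict[str, pd.DataFrame]:
    """All comparison blocks for one dataset (full or culled subset)."""
    fam = {**DEFAULT_FAMILY_SIZES, **cfg.family_sizes}
    alpha = cfg.alpha
    labels = cohort.labels
    keep = set(gene_ids) if gene_ids is not None else None
    genes = [g for g in cohort.genes if keep is None or g.gene_id in keep]
    proteins = [p for p in cohort.proteins if keep is None or p.protein_id in keep]

    out: dict[str, pd.DataFrame] = {}
    gtab = gene_feature_table(genes)
    out[f"{dataset}/gene_features"] = _numeric_block(
        gtab, GENE_FEATURES, labels, fam["gene_features"], alpha)
    ptab = protein_feature_table(proteins)
    out[f"{dataset}/pepstats"] = _numeric_block(
        ptab, PEPSTATS_FEATURES, labels, fam["pepstats"], alpha)
    out[f"{dataset}/amino_acids"] = _numeric_block(
        ptab, [f"aa_{aa}" for aa in STANDARD_AA], labels,
        fam["amino_acids"], alpha)
    out[f"{dataset}/keywords"] = _flag_block(
        proteins, KEYWORD_FLAGS, labels, fam["keywords"], alpha)
    out[f"{dataset}/signal_peptide"] = _flag_block(
        proteins, ("signal_peptide",), labels, 1, alpha)
    out[f"{dataset}/subcellular"] = _flag_block(
        proteins, LOCATION_FLAGS, labels, fam["subcellular"], alpha)
    out[f"{dataset}/housekeeping"] = _flag_block(
        proteins, ("housekeeping", "tissue_enriched"), labels,
        fam["housekeeping"], alpha)

    # enzyme classes as one-vs-rest frequency comparisons
    ess = [p for p in proteins if labels[p.protein_id] == "essential"]
    via = [p for p in proteins if labels[p.protein_id] == "viable"]
    rows = []
    for enz in ENZYME_CLASSES:
        res = compare_categorical(
            sum(p.enzyme_class == enz for p in ess), len(ess),
            sum(p.enzyme_class == enz for p in via), len(via),
            ComparisonSpec(feature=enz, kind="categorical",
                           m=fam["enzyme_class"], alpha=alpha))
        rows.append(_result_row(res))
    out[f"{dataset}/enzyme_class"] = pd.DataFrame(rows).set_index("feature")
    return out


def run(config: RunConfig) -> ReportBundle:
    """Execute the full pipeline under one seed; deterministic."""
    t0 = time.time()
    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic.with_seed(config.seed))
        source = "synthetic"
    else:
        cohort = read_cohort(config.input_dir)
        source = str(config.input_dir)
    log.info("cohort ready: %d genes (%.1fs)", len(cohort.genes),
             time.time() - t0)

    tables = _comparison_tables(cohort, config, "full")

    fam = {**DEFAULT_FAMILY_SIZES, **config.family_sizes}
    tpm_matrix = tpm(cohort.expression)
    tables["full/stage_expression"] = stage_expression_frequencies(
        tpm_matrix, cohort.labels, m=fam["stages"], alpha=config.alpha)

    assignments = [assign_ages(parse_gene_tree(nwk), gid)
                   for gid, nwk in cohort.trees.items()]
    for mode in ("MRD", "DCA"):
        tables[f"full/age_groups_{mode.lower()}"] = age_group_frequencies(
            assignments, cohort.labels, mode=mode, m=fam["age_groups"],
            alpha=config.alpha)

    if config.compute_ppi_metrics:
        t1 = time.time()
        metrics = node_metrics_table(cohort.ppi, config.epc)
        tables["full/ppi_metrics"] = metrics
        lab = cohort.labels
        for name, feats, m in (("ppi_centralities", PPI_CENTRALITIES,
                                fam["ppi_centralities"]),
                               ("ppi_hubs", PPI_HUBS, fam["ppi_hubs"])):
            usable = metrics.dropna(subset=["asp"]) if "asp" in feats else metrics
            tables[f"full/{name}"] = _numeric_block(
                usable, feats, lab, m, config.alpha)
        log.info("ppi metrics done (%.1fs)", time.time() - t1)

    sequences = {p.protein_id: p.sequence for p in cohort.proteins}
    cull_summary = {}
    for threshold in config.culling_thresholds:
        t1 = time.time()
        result = cull_sequences(sequences, threshold)
        retained = sorted(result.retained)
        cull_summary[threshold] = {
            "retained": len(retained),
            "removed": len(result.removed),
        }
        tables.update(_comparison_tables(
            cohort, config, f"culled{int(threshold)}", retained))
        log.info("culled at %s%%: kept %d/%d (%.1fs)", threshold,
                 len(retained), len(sequences), time.time() - t1)

    manifest = {
        "source": source,
        "seed": config.seed,
        "n_genes": len(cohort.genes),
        "n_essential": sum(v == "essential" for v in cohort.labels.values()),
        "n_viable": sum(v == "viable" for v in cohort.labels.values()),
        "family_sizes": fam,
        "culling": cull_summary,
        "alpha": config.alpha,
        "elapsed_s": round(time.time() - t0, 2),
    }
    return ReportBundle(tables, manifest)


def validate_inputs(directory) -> list[str]:
    """Non-mutating diagnostics for an on-disk cohort directory."""
    from pathlib import Path

    directory = Path(directory)
    diags: list[str] = []
    required = ("proteins.fasta", "gene_models.tsv", "expression.tsv",
                "annotations.tsv", "ppi_edges.tsv", "trees.nwk", "labels.tsv")
    for name in required:
        if not (directory / name).exists():
            diags.append(f"error: missing input file {name}")
    if diags:
        return diags

    labels = {}
    with open(directory / "labels.tsv") as fh:
        next(fh)
        for line in fh:
            gid, label = line.rstrip("\n").split("\t")
            labels[gid] = label
            if label not in ("essential", "viable"):
                diags.append(f"error: {gid} has unknown label {label!r}")

    fasta_ids = set()
    with open(directory / "proteins.fasta") as fh:
        for line in fh:
            if line.startswith(">"):
                fasta_ids.add(line[1:].split()[0])
    orphans = sorted(set(labels) - fasta_ids)
    if orphans:
        diags.append(f"warning: labelled genes absent from FASTA: {orphans[:10]}")

    header = pd.read_csv(directory / "expression.tsv", sep="\t", nrows=0)
    stages = [c for c in header.columns if c != "gene_id"]
    missing = [s for s in DEVELOPMENTAL_STAGES if s not in stages]
    if missing:
        diags.append(f"error: expression table missing stages: {missing}")

    try:
        with open(directory / "trees.nwk") as fh:
            for lineno, line in enumerate(fh, 1):
                if line.strip():
                    _, nwk = line.rstrip("\n").split("\t", 1)
                    parse_gene_tree(nwk)
    except Exception as exc:  # diagnostics, not exceptions
        diags.append(f"error: trees.nwk line {lineno}: {exc}")

    with open(directory / "ppi_edges.tsv") as fh:
        next(fh)
        for lineno, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                diags.append(f"error: ppi_edges.tsv line {lineno}: malformed")
                break
    return diags
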