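"""EST expression: TPM normalization, stage frequencies, binned histograms.

TPM_ij = (ESTs for gene i at stage j / total ESTs at stage j) * 1e6, over
the 13 canonical developmental stages.  A gene counts as "expressed" at a
stage iff its TPM (equivalently its EST count) is positive.  The TPM
denominator is the total over the genes present in the table; with a full
compendium this matches the database-wide stage total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._constants import DEVELOPMENTAL_STAGES
from .stats_compare import ComparisonSpec, compare_categorical

__all__ = [
    "ExpressionTable",
    "tpm",
    "stage_expression_frequencies",
    "tpm_histogram",
    "read_expression_table",
    "write_expression_table",
]


@dataclass(frozen=True)
class ExpressionTable:
    """Non-negative integer EST counts, genes x the 13 canonical stages."""

    est_counts: pd.DataFrame

    def __post_init__(self) -> None:
        cols = tuple(self.est_counts.columns)
        if cols != DEVELOPMENTAL_STAGES:
            missing = [s for s in DEVELOPMENTAL_STAGES if s not in cols]
            extra = [s for s in cols if s not in DEVELOPMENTAL_STAGES]
            raise ValueError(
                "expression table must have exactly the 13 canonical stages "
                f"in order; missing={missing}, unexpected={extra}"
            )
        if (self.est_counts.to_numpy() < 0).any():
            raise ValueError("EST counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.est_counts.index)


def tpm(table: ExpressionTable) -> pd.DataFrame:
    """Transcripts-per-million matrix; all-zero stages stay all-zero."""
    counts = table.est_counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(totals > 0, counts / totals * 1e6, 0.0)
    return pd.DataFrame(scaled, index=table.est_counts.index,
                        columns=table.est_counts.columns)


def stage_expression_frequencies(tpm_matrix: pd.DataFrame,
                                 labels: dict[str, str],
                                 m: int = 13,
                                 alpha: float = 0.05,
                                 denominators: dict[str, int] | None = None,
                                 ) -> pd.DataFrame:
    """Percent of each group expressed per stage with per-stage chi-squared.

    ``denominators`` optionally overrides the per-group totals (the study
    exposes these because expression data may cover fewer genes than the
    label file).
    """
    unlabeled = [g for g in tpm_matrix.index if g not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled genes in expression table: {unlabeled[:5]}")
    ess = [g for g in tpm_matrix.index if labels[g] == "essential"]
    via = [g for g in tpm_matrix.index if labels[g] == "viable"]
    n_e = denominators.get("essential", len(ess)) if denominators else len(ess)
    n_v = denominators.get("viable", len(via)) if denominators else len(via)
    rows = []
    for stage in tpm_matrix.columns:
        k_e = int((tpm_matrix.loc[ess, stage] > 0).sum())
        k_v = int((tpm_matrix.loc[via, stage] > 0).sum())
        res = compare_categorical(
            k_e, n_e, k_v, n_v,
            ComparisonSpec(feature=stage, kind="categorical", m=m, alpha=alpha))
        rows.append({
            "stage": stage,
            "pct_essential": res.summary_a,
            "pct_viable": res.summary_b,
            "test": res.test,
            "statistic": res.statistic,
            "p": res.p,
            "threshold": res.threshold,
            "significant": res.significant,
        })
    return pd.DataFrame(rows).set_index("stage")


def tpm_histogram(tpm_matrix: pd.DataFrame,
                  labels: dict[str, str] | None = None,
                  bin_size: float = 50.0) -> pd.DataFrame:
    """Binned counts of (gene, stage) TPM cells, half-open bins [k*b, (k+1)*b).

    With ``labels`` the counts are split per group, otherwise one ``all``
    column.  Conserves the total number of cells.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if tpm_matrix.size == 0:
        return pd.DataFrame(columns=["bin_start"]).set_index("bin_start")
    groups: dict[str, np.ndarray]
    if labels is None:
        groups = {"all": tpm_matrix.to_numpy(dtype=float).ravel()}
    else:
        groups = {
            grp: tpm_matrix.loc[[g for g in tpm_matrix.index
                                 if labels.get(g) == grp]].to_numpy(float).ravel()
            for grp in ("essential", "viable")
        }
    max_bin = max(int(v.max() // bin_size) if v.size else 0
                  for v in groups.values())
    out = {"bin_start": [k * bin_size for k in range(max_bin + 1)]}
    for grp, values in groups.items():
        idx = (values // bin_size).astype(int)
        out[grp] = np.bincount(idx, minlength=max_bin + 1)
    return pd.DataFrame(out).set_index("bin_start")


def read_expression_table(path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(df.astype(int))


def write_expression_table(table: ExpressionTable, path) -> None:
    table.est_counts.to_csv(path, sep="\t", index_label="gene_id")
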