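"""Gene- and protein-level sequence features.

Gene features follow the longest-transcript convention: for a gene with
several transcripts the exon count and total exon length are taken from the
transcript with the greatest total exon length, and the intron length is the
gene length minus that exon total.

Protein features reproduce the classic Pepstats report: molecular weight
(average residue masses plus one water), formal charge at the
(K + R + H/2) - (D + E) convention, isoelectric point by bisection on the
Henderson-Hasselbalch net-charge curve, the 20 standard amino-acid
percentage frequencies, and the nine residue-category percentages (tiny,
small, aliphatic, aromatic, non-polar, polar, charged, basic, acidic) with
the ambiguity codes B and Z counted in the categories that list them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._constants import (
    AVERAGE_RESIDUE_MASS,
    EXTENDED_AA,
    PEPSTATS_CATEGORIES,
    PKA_NEGATIVE,
    PKA_POSITIVE,
    RESIDUE_CHARGE,
    STANDARD_AA,
    WATER_MASS,
)

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "GeneFeatureVector",
    "ProteinRecord",
    "ProteinFeatureVector",
    "gene_features",
    "aa_frequencies",
    "pepstats_features",
    "gene_feature_table",
    "protein_feature_table",
]


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as a list of exon lengths (bp)."""

    exon_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.exon_lengths:
            raise ValueError("transcript must have at least one exon")
        if any(x <= 0 for x in self.exon_lengths):
            raise ValueError("all exon lengths must be > 0")

    @property
    def total_exon_length(self) -> int:
        return sum(self.exon_lengths)


@dataclass(frozen=True)
class GeneModel:
    """One gene: total genomic length, GC fraction and its transcripts."""

    gene_id: str
    gene_length: int
    gc: float
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene must have >= 1 transcript")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"{self.gene_id}: gc must be in [0, 1]")
        longest = max(t.total_exon_length for t in self.transcripts)
        if self.gene_length < longest:
            raise ValueError(
                f"{self.gene_id}: gene_length {self.gene_length} < total exon "
                f"length {longest}"
            )


@dataclass(frozen=True)
class GeneFeatureVector:
    gene_id: str
    gene_length: int
    gc_percent: float
    n_transcripts: int
    n_exons: int
    exon_length: int
    intron_length: int


@dataclass(frozen=True)
class ProteinRecord:
    """Protein sequence plus input-curated annotation flags."""

    protein_id: str
    sequence: str
    flags: dict[str, bool] = field(default_factory=dict)
    enzyme_class: str | None = None
    tm_count: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: sequence must be non-empty")
        if self.tm_count < 0:
            raise ValueError(f"{self.protein_id}: tm_count must be >= 0")


@dataclass(frozen=True)
class ProteinFeatureVector:
    protein_id: str
    length: int
    mw: float
    charge: float
    pi: float
    aa_freq: dict[str, float]
    category_freq: dict[str, float]


def gene_features(gene: GeneModel) -> GeneFeatureVector:
    """Longest-transcript gene features; intron = gene - exon total."""
    longest = max(gene.transcripts, key=lambda t: t.total_exon_length)
    exon_length = longest.total_exon_length
    return GeneFeatureVector(
        gene_id=gene.gene_id,
        gene_length=gene.gene_length,
        gc_percent=round(100.0 * gene.gc, 2),
        n_transcripts=len(gene.transcripts),
        n_exons=len(longest.exon_lengths),
        exon_length=exon_length,
        intron_length=gene.gene_length - exon_length,
    )


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    for i, aa in enumerate(seq):
        if aa not in EXTENDED_AA:
            raise ValueError(f"invalid residue {aa!r} at position {i}")
    return seq


def aa_frequencies(sequence: str) -> dict[str, float]:
    """Percentage frequency of each of the 20 standard residues.

    B and Z are tolerated in the sequence but excluded from both numerator
    and denominator.
    """
    seq = _validate_sequence(sequence)
    n_standard = sum(seq.count(aa) for aa in STANDARD_AA)
    if n_standard == 0:
        return {aa: 0.0 for aa in STANDARD_AA}
    return {aa: 100.0 * seq.count(aa) / n_standard for aa in STANDARD_AA}


def _isoelectric_point(counts: dict[str, int]) -> float:
    """Bisection on the Henderson-Hasselbalch net charge; B/Z count as
    half an Asp/Glu respectively."""
    pos = {"Nterm": 1.0, "K": float(counts.get("K", 0)),
           "R": float(counts.get("R", 0)), "H": float(counts.get("H", 0))}
    neg = {"Cterm": 1.0,
           "D": counts.get("D", 0) + 0.5 * counts.get("B", 0),
           "E": counts.get("E", 0) + 0.5 * counts.get("Z", 0),
           "C": float(counts.get("C", 0)), "Y": float(counts.get("Y", 0))}

    def net_charge(ph: float) -> float:
        q = sum(n / (1.0 + 10.0 ** (ph - PKA_POSITIVE[g])) for g, n in pos.items())
        q -= sum(n / (1.0 + 10.0 ** (PKA_NEGATIVE[g] - ph)) for g, n in neg.items())
        return q

    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if net_charge(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def pepstats_features(sequence: str, protein_id: str = "") -> ProteinFeatureVector:
    """Pepstats-style report for one sequence."""
    seq = _validate_sequence(sequence)
    n = len(seq)
    counts = {aa: seq.count(aa) for aa in EXTENDED_AA}
    mw = sum(c * AVERAGE_RESIDUE_MASS[aa] for aa, c in counts.items()) + WATER_MASS
    charge = sum(c * RESIDUE_CHARGE.get(aa, 0.0) for aa, c in counts.items())
    category_freq = {
        name: 100.0 * sum(counts[aa] for aa in members) / n
        for name, members in PEPSTATS_CATEGORIES.items()
    }
    return ProteinFeatureVector(
        protein_id=protein_id,
        length=n,
        mw=mw,
        charge=charge,
        pi=_isoelectric_point(counts),
        aa_freq=aa_frequencies(seq),
        category_freq=category_freq,
    )


def gene_feature_table(genes: list[GeneModel]) -> pd.DataFrame:
    """One row per gene, columns named as in the study's gene feature table."""
    rows = [gene_features(g) for g in genes]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "gene_length": [r.gene_length for r in rows],
            "gc_percent": [r.gc_percent for r in rows],
            "n_transcripts": [r.n_transcripts for r in rows],
            "n_exons": [r.n_exons for r in rows],
            "exon_length": [r.exon_length for r in rows],
            "intron_length": [r.intron_length for r in rows],
        }
    ).set_index("gene_id")


def protein_feature_table(proteins: list[ProteinRecord]) -> pd.DataFrame:
    """One row per protein: length, MW, charge, pI, 20 aa %, 9 category %."""
    rows = [pepstats_features(p.sequence, p.protein_id) for p in proteins]
    data: dict[str, list] = {
        "protein_id": [r.protein_id for r in rows],
        "length": [r.length for r in rows],
        "mw": [r.mw for r in rows],
        "charge": [r.charge for r in rows],
        "pi": [r.pi for r in rows],
    }
    for aa in STANDARD_AA:
        data[f"aa_{aa}"] = [r.aa_freq[aa] for r in rows]
    for cat in PEPSTATS_CATEGORIES:
        data[cat] = [r.category_freq[cat] for r in rows]
    return pd.DataFrame(data).set_index("protein_id")
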