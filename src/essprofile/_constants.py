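"""Shared physical constants and study-design tables.

One place for the amino-acid mass/pKa tables (EMBOSS Pepstats-compatible
defaults), the nine residue category sets, the 13 canonical developmental
stages, the 16-row phylogenetic age table, and the default two-group rates
used by the synthetic cohort generator.
"""

from __future__ import annotations

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED_AA = STANDARD_AA + "BZ"

# Average (isotope-weighted) residue masses in Da; water added once per chain.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
AVERAGE_RESIDUE_MASS["B"] = (AVERAGE_RESIDUE_MASS["N"] + AVERAGE_RESIDUE_MASS["D"]) / 2
AVERAGE_RESIDUE_MASS["Z"] = (AVERAGE_RESIDUE_MASS["E"] + AVERAGE_RESIDUE_MASS["Q"]) / 2
WATER_MASS = 18.0153

# EMBOSS-style side-chain / terminus pKa values used for the pI bisection.
PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

# Per-residue formal charge convention: (K + R + H/2) - (D + E), with the
# ambiguity codes B (Asx) and Z (Glx) counted as half an acidic residue.
RESIDUE_CHARGE = {"K": 1.0, "R": 1.0, "H": 0.5, "D": -1.0, "E": -1.0,
                  "B": -0.5, "Z": -0.5}

# Pepstats residue category sets (exact membership, including B and Z).
PEPSTATS_CATEGORIES = {
    "tiny": set("ACGST"),
    "small": set("ABCDGNPSTV"),
    "aliphatic": set("ILV"),
    "aromatic": set("FHWY"),
    "non_polar": set("ACFGILMPVWY"),
    "polar": set("DEHKNQRSTZ"),
    "charged": set("BDEHKRZ"),
    "basic": set("HKR"),
    "acidic": set("BDEZ"),
}

# The 13 developmental stages, in canonical order.
DEVELOPMENTAL_STAGES = (
    "oocyte", "unfertilized ovum", "zygote", "cleavage", "morula",
    "blastocyst", "egg cylinder", "gastrula", "organogenesis", "fetus",
    "neonate", "juvenile", "adult",
)

# Phylogenetic age groups (taxon label, age in MYA), youngest to oldest.
TAXON_AGES = (
    ("Murinae", 25.0),
    ("Rodentia", 77.0),
    ("Sciurognathi", 78.0),
    ("Glires", 86.0),
    ("Euarchontoglires", 92.0),
    ("Eutheria", 104.0),
    ("Theria", 162.0),
    ("Mammalia", 167.0),
    ("Amniota", 296.0),
    ("Tetrapoda", 371.0),
    ("Euteleostomi", 400.0),
    ("Sarcopterygii", 414.0),
    ("Vertebrata", 535.0),
    ("Chordata", 722.0),
    ("Bilateria", 937.0),
    ("Opisthokonta", 1215.0),
)
TAXON_BY_AGE = {age: taxon for taxon, age in TAXON_AGES}

GROUPS = ("essential", "viable")

# ---------------------------------------------------------------------------
# Default effect sizes for the synthetic cohort generator.  Tuples are
# (essential, viable).  Medians/rates follow the published mouse study
# contrasts so the generator's defaults ARE the study conditions.
# ---------------------------------------------------------------------------

DEFAULT_GENE_LENGTH_MEDIAN = (28913.0, 21629.0)
DEFAULT_EXON_TOTAL_MEDIAN = (3398.0, 2780.0)
DEFAULT_TRANSCRIPT_COUNT_MEAN = (4.0, 2.0)
DEFAULT_EXON_COUNT_MEAN = (11.0, 8.0)
DEFAULT_GC_MEAN = (0.4646, 0.4716)

# 20-aa mean composition (%) per group; Dirichlet alpha = freq/100 * concentration.
DEFAULT_AA_PERCENT = {
    "A": (6.87, 6.74), "C": (1.88, 2.08), "D": (4.91, 4.73), "E": (6.68, 6.22),
    "F": (3.39, 3.80), "G": (6.43, 6.49), "H": (2.48, 2.39), "I": (4.06, 4.24),
    "K": (5.67, 5.15), "L": (9.31, 10.00), "M": (2.19, 2.21), "N": (3.63, 3.50),
    "P": (5.86, 5.72), "Q": (4.48, 4.25), "R": (5.41, 5.38), "S": (8.01, 7.78),
    "T": (5.14, 5.24), "V": (5.89, 6.25), "W": (1.01, 1.31), "Y": (2.73, 2.83),
}

# Bernoulli annotation flag rates (essential, viable).
DEFAULT_ANNOTATION_RATES = {
    "phosphoprotein": (0.514, 0.355),
    "glycoprotein": (0.213, 0.382),
    "acetylation": (0.289, 0.129),
    "transcription": (0.278, 0.115),
    "signal_peptide": (0.164, 0.291),
    "housekeeping": (0.117, 0.163),
    "tissue_enriched": (0.342, 0.438),
    "loc_nucleus": (0.482, 0.236),
    "loc_cytoplasm": (0.333, 0.294),
    "loc_plasma_membrane": (0.131, 0.233),
    "loc_extracellular": (0.073, 0.146),
}

# Probability of carrying at least one transmembrane segment.
DEFAULT_TM_RATE = (0.20, 0.34)

# Top-level enzyme class probabilities; remainder = non-enzyme.
DEFAULT_ENZYME_PROBS = {
    "oxidoreductase": (0.034, 0.037),
    "transferase": (0.135, 0.101),
    "hydrolase": (0.081, 0.109),
    "lyase": (0.0131, 0.0110),
    "isomerase": (0.0069, 0.0067),
    "ligase": (0.029, 0.012),
}
ENZYME_CLASSES = tuple(DEFAULT_ENZYME_PROBS)

# Fraction of genes expressed (EST count > 0) per stage, per group.
DEFAULT_EXPRESSED_FRACTION = {
    "oocyte": (0.420, 0.209),
    "unfertilized ovum": (0.263, 0.105),
    "zygote": (0.353, 0.178),
    "cleavage": (0.455, 0.232),
    "morula": (0.436, 0.197),
    "blastocyst": (0.598, 0.304),
    "egg cylinder": (0.224, 0.083),
    "gastrula": (0.571, 0.293),
    "organogenesis": (0.838, 0.541),
    "fetus": (0.973, 0.864),
    "neonate": (0.850, 0.707),
    "juvenile": (0.924, 0.878),
    "adult": (0.959, 0.941),
}

# Phylogenetic root-age weights per group (MRD+SCA frequency columns, %).
DEFAULT_AGE_WEIGHTS = {
    25.0: (0.63, 2.17), 77.0: (0.0, 0.09), 78.0: (0.0, 0.06),
    86.0: (0.24, 0.06), 92.0: (0.55, 0.51), 104.0: (11.60, 11.23),
    162.0: (1.25, 2.80), 167.0: (3.45, 5.03), 296.0: (5.41, 4.79),
    371.0: (1.41, 2.56), 400.0: (31.58, 41.69), 414.0: (1.80, 2.74),
    535.0: (13.48, 14.80), 722.0: (4.00, 3.25), 937.0: (15.67, 6.08),
    1215.0: (8.93, 2.14),
}
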