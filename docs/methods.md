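# Methods

This note documents the models, conventions and numerical choices behind
`essprofile`, and what the synthetic cohorts do and do not establish about
real data.

## The comparison framework

Every analysis reduces to a two-group contrast between essential and
viable genes. Numeric features pass a normality gate: a one-sample
Kolmogorov–Smirnov test against a normal with sample-estimated mean and
SD. Because estimating the parameters from the same sample makes the
plain K-S p-value anti-conservative, the gate uses the Lilliefors-corrected
variant by default (`normality_gate(..., lilliefors=False)` exposes the
uncorrected test for fidelity to the classical recipe). Samples below
n = 8 are treated as non-normal rather than gated. If both samples pass,
Welch's unequal-variance t is used; otherwise the two-tailed Mann–Whitney
U — exact enumeration when both samples have ≤ 20 tie-free observations,
else the normal approximation with tie correction and **no** continuity
correction (the convention of the classic statistics packages this
pipeline mirrors).

Categorical features use Pearson's χ² on the 2×2 table without Yates
correction. The Fisher-exact fallback triggers when any expected cell is
below 5 **or** any observed cell is zero; a zero observed cell is the
textbook indication for an exact test even when the expected counts are
exactly at the boundary. A 2×2 table with an empty margin is degenerate
and reported as χ² = 0, p = 1.

Multiple testing is controlled per family with the Bonferroni threshold
α/m applied to the raw p-value (significant ⇔ p ≤ α/m), matching how the
study tables present significance. Family sizes default to: gene features
6, Pepstats features 13 (the published threshold 0.0038 = 0.05/13 fixes
m = 13 even though fewer columns are printed; the size is configurable),
amino acids 20, developmental stages 13, age groups 16, PTM/transcription
keywords 4, enzyme classes 6, subcellular locations 12, housekeeping
block 2, PPI centralities 5, PPI hub scores 4. Term enrichment instead
reports DAVID-style inflated p-values min(1, m·p) from a one-tailed
Fisher test, sorted by corrected p.

## Sequence features

Gene features follow the longest-transcript convention: exon count and
total exon length come from the transcript with the greatest exon total;
intron length is gene length minus that total and is non-negative by the
gene-model invariant. GC is reported as a percentage with two decimals.

Protein molecular weight sums average residue masses plus one water
(G = 57.0519 Da, water = 18.0153 Da, etc.); B and Z take the mean of
their two parent residues. Charge uses the integer convention
(K + R + H/2) − (D + E), with B and Z counting −0.5. The isoelectric
point bisects the Henderson–Hasselbalch net charge on pH ∈ [0, 14] with
EMBOSS-style pKa values (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5,
D 3.9, E 4.1, C 8.5, Y 10.1); 100 bisection steps give ~1e-28 pH
resolution. The nine residue categories use their exact published
memberships including B and Z; the 20-residue frequency table excludes
B/Z from numerator and denominator, so `non_polar + polar = 100` holds
for standard-alphabet sequences (B belongs to neither set).

## Redundancy culling

Percent identity is 100 × matches / alignment length from a global
alignment (BLOSUM62, gap open 10, extend 0.5). Using the alignment length
(gaps included) as the denominator rather than the shorter sequence
length is the conservative choice: it can only lower identities
symmetrically and is stated here because it changes edge sets near a
threshold. Culling treats the ≥-threshold pairs as a graph and removes a
vertex set leaving an independent set: components with ≤ 12 vertices are
solved exactly for the maximum independent set by bitmask enumeration
(≤ 4096 subsets); larger components fall back to greedy removal of the
highest-degree vertex, ties broken by removing the lexicographically
smallest identifier, which makes the whole procedure deterministic.
Thresholds below 20 % identity are rejected — below the twilight zone,
identity no longer implies redundancy. All-pairs alignment is quadratic
(~16 ms per ~1000-residue pair), so the bundled demonstrations and tests
cull cohorts of tens-to-hundreds of sequences; the algorithm itself has
no size limit.

## Expression

TPM normalizes each stage column by that column's EST total; an all-zero
stage stays all-zero rather than dividing by zero. The denominator is the
total over the genes present in the table — with a full compendium this
equals the database-wide stage total, with a subset it is a per-dataset
renormalization; the semantic difference is deliberate and documented.
"Expressed" means TPM > 0 (equivalently ESTs > 0): no abundance floor is
imposed, consistent with treating zero-transcript genes as the
unexpressed class. Per-group stage denominators can be overridden because
expression coverage may be smaller than the label file. Histograms use
half-open bins [k·b, (k+1)·b) with b = 50 by default.

## Evolutionary age

Trees arrive as Newick with `[&age=<MYA>,event=<duplication|speciation>]`
hot comments on internal nodes and must be ultrametrically ordered (ages
non-increasing towards the leaves). MRD is the age of the nearest
duplication ancestor of the gene's leaf, DCA the farthest; a gene with no
duplication ancestor takes the root age (SCA) for both, which is the only
root-level information a single gene tree carries. Ages map to the 16
canonical age groups by exact match by default — a non-tabulated age is
treated as a data error — with `snap=True` available to snap to the
nearest tabulated age. Frequency tables always report all 16 rows, even
those with zero mass.

## PPI topology

Graphs are cleaned to simple undirected form (self-loops and duplicate or
reversed edges dropped, with counts reported). Betweenness follows the
shortest-path-ratio sum normalized by (N−1)(N−2)/2 so values land in
[0, 1] as the metric's description requires, with N the full node count.
Closeness is implemented literally as 1/Σd within the node's connected
component — the equation wins over the "average" wording — and the
conventional (n−1)/Σd form is exposed via a flag. Isolated nodes score 0
for betweenness, clustering and closeness, and their ASP is missing
(NaN), which downstream comparisons drop.

BottleNeck builds one BFS shortest-path tree per root with a
deterministic parent rule (lexicographically smallest candidate at the
previous level); node b scores for root r when its descendant count
(excluding b itself) is at least n_r/4, n_r being the tree size. Both the
tree-size convention and the self-exclusion are stated because the metric
is tie-sensitive: BN is the one score that is reproducible only for a
fixed input ordering, which the deterministic parent rule provides.

EPC is a seeded Monte Carlo: each of n replicates (default 100) keeps
every edge independently with retention probability 0.5 (both
configurable — the original tool's internals are unpublished), and
EPC(v) averages the number of nodes still connected to v. Retention 1
therefore returns component size − 1 exactly, retention 0 returns 0, and
on a single edge the estimate converges to the retention probability at
the binomial rate. MNC is the largest component of the open neighbourhood
subgraph; DMNC divides that component's edge count by its node count
raised to 1.7, and is 0 whenever the component has ≤ 1 node or no edges.

## The synthetic cohort generator

The generator exists to exercise the pipeline under a known ground truth,
with defaults set to the published study conditions: 1301 essential and
3451 viable genes; median gene lengths 28913/21629 bp and exon totals
3398/2780 bp; transcript and exon count means 4/2 and 11/8; GC means
46.46/47.16 %; 20-dimensional Dirichlet amino-acid compositions centred
on the published group frequencies (concentration 300, chosen so
per-protein composition scatter is a few percent — the study reports no
dispersions, so this and the log-normal σ values 0.8/0.5 for gene/exon
lengths are free realism parameters, set once); Bernoulli annotation
flags at the published group rates (signal peptide 0.164/0.291,
phosphoprotein 0.514/0.355, nucleus 0.482/0.236, …); zero-inflated
gamma-Poisson EST counts (shape 0.5) whose stage means are inverted from
the published per-stage expressed fractions; a preferential-attachment
PPI graph (3 edges per arriving node) where essential nodes carry a
fitness multiplier of 2, qualitatively reproducing hub enrichment; and
gene trees whose root/duplication ages are drawn from the published
16-age frequency columns, with duplication probability 0.6 so both the
MRD≠DCA and the SCA fallback paths are exercised. Protein length is the
principal exon total / 3 (floor, minimum 30 aa), keeping gene and protein
features coherent; a 15 % paralog rate copies an earlier same-group
sequence with 8 % substitutions so the culling stage has real redundancy
to find.

What passing tests on these cohorts show: the extractors, the statistics
and the multiple-testing control recover configured effects with correct
direction and calibrated type-I error. What they do not show: anything
about real mouse sequence content, real tree topologies, correlated
feature structure (features are generated independently given the group),
or the database-snapshot-dependent medians and percentages of the
original datasets — those are inputs, not predictions, here.

Sample-size choices in the shipped tests and acceptance script (80/group
for the 200-seed null calibration, 500/group for direction/power, 250/group
for median recovery) are the package's own trade-off between Monte-Carlo
resolution and runtime; all are configurable. Under the null, four
mutually independent gene features per seed give ~800 approximately
independent rejection trials, compared against the central 99 % binomial
band at α = 0.05. Direction/power checks demand each expected tendency in
≥ 9 of 10 seeds; contrasts whose published effect sizes yield < 90 %
analytic power at n = 500/group (GC — non-significant in the source
conditions as well — housekeeping, tissue-enriched, and single-residue
frequencies) are held to the direction check only.

## Known limitations

- The culling heuristic is optimal only on small components; on large
  dense components greedy removal can retain slightly fewer sequences
  than the true maximum independent set (the validity guarantee — no
  retained pair at/above threshold — always holds).
- EPC inherits Monte-Carlo noise of order sqrt(component size / n)
  per node; comparisons across groups average this out but individual
  node scores at the default n = 100 are coarse.
- The normality gate's table-based Lilliefors p-values saturate at large
  n; for the feature families here (heavily non-normal) the gate's role
  is to route to the rank test, which it does robustly.
- Generated annotation flags are independent Bernoulli draws; real
  annotations are correlated (e.g. signal peptide with extracellular
  location), so joint-feature analyses on synthetic cohorts are not
  informative.
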