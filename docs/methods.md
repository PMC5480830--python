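# Methods

`mirevol` re-implements, as a tested library, the comparative workflow used
to study microRNA evolution across a primate-like clade: cluster
experimentally supported mature miRNAs into homolog families, subdivide
them into ortholog groups, call substitution variants within the mature
region and classify them by functional region, score the structural
conservation of the precursor hairpins, call paralog loci present or
absent across genomes using conserved flanking sequence as the anchor, and
build distance trees. A ground-truthed simulator generates study-shaped
data so that every stage is testable without external downloads.

## Sequence model and coordinates

The internal alphabet is DNA (`T`, never `U`); RNA input is converted at
the I/O boundary, since genomic windows and small-RNA reads mix
conventions. All internal coordinates are 0-based half-open; all report
output is 1-based, with position 1 the 5' end of the mature strand.
Functional regions of the mature miRNA follow the standard numbering:
seed = positions 1–8, central = 9–12, 3' supplementary = 13–16,
tail = 17 to the mature 3' end.

## Alignment and homology

Pairwise alignment (local and global) is delegated to Biopython's
`PairwiseAligner` with match +1, mismatch −1, gap open −2, gap extend −1
(configurable). Identity is defined as matched columns / aligned columns,
counting gap columns as mismatches — the stricter of the common
conventions. Homolog clustering retains all-versus-all local hits at
≥ 70% identity over ≥ 18 aligned columns and takes connected components
(single linkage: a sequence joins a group if it matches *any* member).
Multiple alignment uses a center-star strategy (align everything to the
sequence with the highest mean pairwise identity and merge with
once-a-gap-always-a-gap), which is essentially exact for the
near-identical, nearly equal-length sequences aligned here.

Two thresholds in this stage are reproducible stand-ins for steps the
original workflow performed by expert inspection:

* **Ortholog subdivision** re-clusters each homolog family at ≥ 0.85
  global identity, keeps one representative per species (highest mean
  identity to the component, ties broken by read depth then id), and
  drops components represented in fewer than 3 species.
* **Confirmation of predicted miRNAs** requires 100% identity over
  ≥ 18 nt. This is implemented as a longest-common-substring search, not
  via the scored local aligner: a score-optimal alignment can extend
  through a mismatch and hide a perfect 18-mer that a conservative
  exact-match criterion must see. Paralog families are collapsed to their
  single best-scoring member.

A caveat worth knowing: on ~22-nt sequences, a 70%-over-18 local match
occasionally arises between unrelated families by chance, and single
linkage will then merge them. This is a property of the criterion, not a
bug; the subdivision stage separates such chance merges cleanly (global
identity between unrelated families is near 25–50%, far below 0.85).
Recovery guarantees are therefore stated at the ortholog-group level —
the grouping the downstream analyses actually consume.

## Variant calling

Within each ortholog group the mature sequences are aligned; per column
the reference base is the majority base (ties broken by a designated
reference species if given, else alphabetically), and each minority base
becomes one variant record listing every species that carries it.
Positions are indexed on the ungapped consensus. Indel columns are
reported separately — the variant table proper contains substitutions
only. Summaries count variants per region and per position, and
variant–species *pairs* per lineage (a variant carried by three species
contributes three pairs), which is the accounting needed to reproduce the
published per-lineage totals from a per-variant table.

## Structure: energy model, z-score, SCI

The folding engine is a weighted Nussinov dynamic program: each canonical
pair contributes a fixed score (GC −3, AU −2, GU −1), structures are
nested with a minimum hairpin loop of 3, and the "MFE" is the minimum
total pair score. This is deliberately not a nearest-neighbor
thermodynamic model: it is brute-force verifiable (an exhaustive
enumerator for ≤ 14 nt serves as the test oracle, with exact agreement
required), and the statistics built on it are model-relative, so their
defining properties — not absolute kcal/mol values — are what the tests
assert. Traceback is deterministic (prefer leaving the 5' base unpaired,
then pairing it with the smallest admissible partner).

* **z-score**: the number of standard deviations between a sequence's
  fold energy and the energy distribution of its shuffled versions. The
  null is a Monte-Carlo Altschul–Erickson dinucleotide-preserving shuffle
  (seedable; preserves the exact dinucleotide multiset and both terminal
  residues). Dinucleotide preservation is stricter than plain
  mononucleotide composition and is the standard choice for structured
  RNA nulls; a mononucleotide permutation mode would be a one-line
  variant. If the shuffle energies are degenerate (sd < 1e−9, e.g.
  homopolymers) the z is reported as 0 with a flag. The null's mean z on
  random sequences sits slightly above 0 (≈ +0.2) because the
  fixed-endpoint Eulerian shuffle is not exactly exchangeable with the
  observed sequence; the calibration band used in testing ([−0.5, 0.5])
  accounts for this.
* **Consensus folding and SCI**: the consensus structure of an alignment
  is folded over column pairs, where a column pair scores the mean of the
  row-wise pair scores (0 for rows gapped or non-canonical there) plus a
  covariance term −b·(t−1) + q·m, with t the number of distinct canonical
  pair types among pairable rows, m the number of non-pairable rows, and
  b = q = 1 by default; a column pair is admissible only if more than half
  the rows can pair. The covariance term rewards compensatory and
  consistent substitutions and penalizes pair-breaking ones; the
  *covariance contribution* reported is its total over consensus pairs
  (negative = compensatory evolution). SCI = consensus energy / mean
  individual fold energy; 1 for perfectly conserved structure, undefined
  (flagged) when the mean individual energy is ~0. Mean pairwise identity
  counts identical non-gap columns over columns where at least one row
  has a base; gap-vs-gap columns are excluded.
* **Excision windows**: candidate hairpin windows around a read stack are
  cut twice, with 20 nt upstream / 70 nt downstream flank and vice versa
  — the two registers in which a stack can sit on the 5' or 3' arm —
  truncated and flagged at contig edges.
* **Seed shift**: hairpins of an ortholog group are multiply aligned and
  each species' mature start is mapped to an alignment column; a species'
  shift is the signed offset of that column from the modal column.
  Working in column space means an indel upstream of the mature does not
  masquerade as a register shift.

## Paralog presence/absence

A locus query (pre-miRNA plus flanking sequence, 400 nt each side by
default at simulation scale; ~1000 nt is typical with real genomes) is
scanned against each genome with the local aligner, iteratively masking
the best hit to recover multiple matches. Alignments are split into
HSP-like pieces at gaps longer than 30 nt — an affine-gap aligner
otherwise bridges a deleted pre-miRNA with one long gap and the match
would spuriously "overlap" the element. Retained matches need ≥ 70%
identity over ≥ 300 columns. Query sub-regions hit more than `max_hits`
(default 100) times are treated as repetitive and their matches dropped.
Calling: a match overlapping the pre-miRNA span of the query by ≥ 10 nt
(a 1–2 nt chance extension of a flank hit is not evidence) → `present`;
otherwise a flank match anchors the hypothetical location of the
pre-miRNA on the target (−100/+200 nt around its expected start), the
pre-miRNA is aligned into that window, and it is rescued as `present`
only at ≥ 0.70 identity over ≥ 60% of its length, else
`absent_flanks_conserved`; no matches at all → `not_found`. Scanning is
single-strand: the simulator never reverse-complements loci, and callers
with real genomes should scan both orientations themselves.

## Trees

p-distances (1 − pairwise identity, same pair rule as above) feed a
hand-written canonical neighbor-joining with a deterministic tie-break
(the pair whose smallest-leaf labels sort lexicographically first is
joined) and negative branch lengths clamped to zero with a flag. NJ on an
additive matrix provably returns the generating tree; the tests assert
exact metric and topology recovery on random additive matrices. Trees
here serve grouping and visualization, as in the original workflow;
likelihood inference is out of scope.

## The simulator and what it does (not) show

`synthetic_data` evolves perfect-stem hairpins (stem 36, loop 11 →
pre-miRNA 83 nt; mature = the outermost 22 nt of the 5' arm) embedded in
random 400 nt flanks, along a fixed 13-taxon tree whose topology mirrors
the ape / Old World monkey / New World monkey / Strepsirrhine splits
(branch lengths invented; most distant pair ≈ 0.57 path length).
Defaults, chosen to emulate the study's qualitative findings:

| parameter | default | meaning |
|---|---|---|
| seed rate | 0.01 | subs/site/unit length, mature 1–8 (most conserved) |
| supplementary rate | 0.05 | mature 13–16 |
| central/tail rate | 0.15 | mature 9–12 and 17+, and non-mature stem |
| loop rate | 0.35 | hairpin loop |
| flank rate | 0.35 | genomic flanks |
| compensatory prob | 0.5 | paired-site substitution restores pairing |
| families | 20 | ancestral hairpins |

Star-arm sites inherit the constraint of their paired mature partner, so
compensation flows in both directions. Substitution counts per site are
Poisson(rate × branch length) with uniform replacement (Jukes–Cantor
flavour, no transition bias by default); compensation is instantaneous
(no intermediate broken-pair state). There are no indels within loci.
Duplications copy the pre-miRNA into fresh random flanks (a dispersed
duplication, the pattern of miRNA families spread across chromosomes);
deletions remove the pre-miRNA and keep the flanks — exactly the
conserved-flank insertion/deletion signature the paralog caller is meant
to recognize. Register-shift events displace the annotated mature start
within the hairpin.

Ancestral matures are not independent random draws: unrelated random
22-mers pass a 70%-over-18 local-identity filter by chance often enough
that single linkage would weld families together in most simulations.
The generator therefore separates ancestors with a local-search guard
(no ≥ 13-column window at ≥ 0.65 identity between families, counting
two-piece gapped windows), which emulates the real situation in which
distinct miRNA families are well separated in sequence space.

What passing recovery tests show: the pipeline's operations are correct
and consistent with each other under the model above. What they do not
show: robustness to indels inside mature sequences, sequencing error,
expression dropout, multi-copy tandem repeats, strand flips, or real
genome complexity — none of which the simulator emulates.

## Numerical choices

Scores are small floats; traceback comparisons use a 1e−9 tolerance.
Degenerate cases are explicit: z-score sd < 1e−9 → z = 0 with flag; SCI
with |mean individual energy| < 1e−9 → undefined with flag; NJ negative
branch lengths → clamped to 0 with flag; FASTA output wraps at 60
columns. Determinism: every stochastic component takes a seed or a
`numpy.random.Generator`; the pipeline is a pure function of (inputs,
config), and repeated simulator runs with the same parameters produce
byte-identical bundles.

## Problem sizes used in the shipped checks

The packaged checks run at desk scale, chosen to exercise every code
path: 500 random sequences against the brute-force folding oracle
(length ≤ 12), 200 shuffles for dinucleotide preservation, 100 random
60-mers × 50 shuffles for z-null calibration, 50 random additive
matrices (5–10 taxa) for NJ, and simulations of 20 families × 13 taxa
(clustering/variants) and 4 families with duplication + deletion events
(presence calling). Study-scale headline numbers (hundreds of validated
miRNAs per species) depend on sequencing reads that were never publicly
released and cannot be recomputed here; the published mature-variant
table, which is self-contained, is packaged as a fixture and its summary
statistics are reproduced exactly.
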