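# Methods

## Coordinate model

All external coordinates are 1-based inclusive (NCBI/GFF3 style). The
promoter axis is relative to the transcription start site and has no
position 0: +1 is the TSS (the annotated gene boundary — `start` for
plus-strand genes, `end` for minus-strand genes) and −1 is the base
immediately 5' of it. The default window −4,900..+100 therefore holds
exactly 5,000 nt. For a plus-strand gene, relative position r maps to
genomic `start + r` (r < 0) or `start + r − 1` (r > 0); the minus
strand mirrors this around `end`, and the extracted sequence is
reverse-complemented so every window reads 5'→3' in transcription
sense. The map is bijective on realized positions and is property-tested
round-trip in both directions.

One window is extracted per gene, anchored at the annotated gene
boundary, not per transcript: the method operates on gene-level
coordinates, and alternative TSSs are out of scope. Windows running off
a chromosome end are clipped and flagged (`truncated_5p`/`truncated_3p`)
— padding would fabricate sequence. Windows may overlap neighbouring
genes; no intergenic-distance trimming is attempted. Published
upstream-interval tables for human hypoxia-inducible genes print
5,001-nt intervals (a zero-containing axis); on the no-zero axis the
same window is that interval minus its single most-3' base, and the
test suite pins this correspondence for all 30 published rows.

## Motif grammar and scanning

HRE = `RCGTG` (2 matching 5-mers), HAS = `CA(G|C)(A|G)(T|G|C)` (12
matching 5-mers). Scanning is by regex lookahead so overlapping
occurrences are all reported; an enumeration oracle (every 5-window
tested against the exhaustive match sets) defines the scanner's
behaviour unambiguously and is asserted on random sequence. Only the
gene-sense strand is scanned — the biological signal is defined
relative to the transcribed gene, and the complementary strand is
deliberately not searched. Positions holding non-ACGT letters
(N or other IUPAC codes) never match.

An RCGTG hit whose immediately preceding window base is C is
reclassified **E-box** (`C·RCGTG`); a hit at the window's first
position has no context base and stays HRE. E-box hits are excluded
from the HRE gene set and from HRE–HAS linking: this is the only
classification under which the four gene-set counts the method reports
(all / HRE / HRE+HAS / E-box) are mutually consistent, and it reflects
HIF's lack of affinity for the E-box. The identity
`genes(HRE) ∪ genes(EBOX) = genes(any RCGTG)` is enforced by test.

**Linking.** The gap between an HRE and a downstream HAS counts the
nucleotides strictly between the HRE 3' end and the HAS 5' start.
Defaults are 7–15 nt; the looser readings that appear in practice
(anything within 15 nt, or within a 30-nt stretch) are reachable by
configuration (`min_gap=0`, `max_gap=15` or `max_gap=30`) rather than
hard-coded. Every qualifying (HRE, HAS) combination is reported; one
HRE may pair with several HAS and vice versa. Widening the gap window
can only add pairs (property-tested monotonicity).

**Regions.** Hits are labelled by their 5' base: core (−900..+100],
proximal (−2,900..−900], distal [−4,900..−2,900], lower bounds
exclusive except the distal floor. On the no-zero axis these realized
sizes are 999 / 2,000 / 2,001 nt (nominally 1,000 / 2,000 / 2,000);
under a uniform null, sites land 19.98 / 40.0 / 40.02% — the geometric
baseline against which an observed enrichment (e.g. elevated core
density near the TSS) is read. The acceptance script recomputes this
null at n = 10,000.

## Gene filtration

Rules run in fixed order — unplaced → mitochondrial → housekeeping by
symbol → housekeeping by mRNA homology — and a gene is charged to the
first rule that removes it, so per-rule counts are disjoint and sum to
the input count (invariant checked on every run). Mitochondrial
detection defaults to an "MT"-containing accession plus an optional
explicit accession set, since annotation conventions vary. Symbol
matching is case-insensitive and exact; LOC-style placeholders only
match if literally listed. The homology screen removes a gene if any of
its mRNAs aligns to any reference housekeeping mRNA at ≥80% identity
over ≥50% of the shorter sequence; both thresholds are configurable.
The 80% default is the same identity used for ortholog calling; the
coverage guard suppresses spurious short local hits.

Alignment is Biopython's local `PairwiseAligner` (match +1, mismatch
−1, gap −2); identity = matches / alignment columns, coverage = columns
/ shorter length. Exact scores are not load-bearing — every decision is
thresholded — and a precomputed 12-column tabular alignment file can
replace the builtin aligner (`backend="table"`), applying the same
thresholds to its `pident`/`length` columns.

## Summaries

Venn accounting uses four gene sets: ALL, HRE (≥1 non-E-box RCGTG),
HAS_LINKED (≥1 linked pair — the "HRE with HAS" reading; a
free-standing HAS count is also kept per gene for the literal reading),
and EBOX. Positional profiles bin hit 5' positions in 500-nt steps over
the window (100-nt bins over −400..+100 for the TSS zoom). Fragments
for de novo motif analysis take 10 positions up to and including the
HRE 3' end plus 30 after it (40 nt total, configurable); fragments
crossing the realized window edge are dropped and counted.

## Comparative analysis

Ortholog mapping is one-directional best-hit by mRNA identity at ≥80%
(ties: coverage, then lexicographic subject ID; reciprocal-best is an
off-by-default flag). Symbol equality is never used — cross-species
placeholder symbols make it unreliable. Re-mining a prepared
reference-species gene table uses the identical pipeline and flags
genes with no RCGTG at all, genes whose HREs all lie outside the core,
and genes with a core-anchored linked pair. Conservation scoring
aligns each query HRE ±10 nt of flank against every subject HRE
fragment and calls a site conserved at ≥80% best flank identity;
flank size mirrors the upstream half of the de novo fragment window and
the threshold reuses the homology identity default.

## Synthetic data

The generator plants HRE, HRE+HAS (chosen gap), E-box and free-standing
HAS motifs at requested relative positions on either strand, then fills
the rest of each window with GC-weighted background (default 41% GC)
and resamples any background base participating in an unplanned
HRE/HAS 5-mer — or sitting as a C immediately before a planted HRE —
until none remains. Ground truth is therefore exact: scanning must
reproduce the manifest with zero false positives/negatives, which is
the package's master end-to-end test. E-box plants use the `CGCGTG`
form; the canonical `CACGTG` embeds a HAS 5-mer (`CACGT`) inside the
planted bases and would violate the clean-background guarantee.
Implied HRE–HAS pairs are enumerated into the manifest by brute force
under the default 7–15 gap rule. A single integer seed drives all
randomness; identical seeds give byte-identical files.

What the generator does **not** emulate: realistic promoter
composition (CpG islands, TATA boxes), motif-density gradients toward
the TSS, assembly gaps, or overlapping gene architectures. Passing the
planted-truth tests demonstrates the machinery is exact, not that any
particular genome shows a particular region split or gene-set size —
genome-scale totals depend on the assembly and annotation release used.

## Problem sizes and numerics

The default test and acceptance workloads use 80–120 synthetic genes
(two chromosomes, both strands, ≥200 planted sites), 1,000 random
200-mers for the oracle comparison and 10,000 draws for the uniform
null; these sizes make every run complete in seconds while keeping
binomial error on the null percentages well under a percentage point.
Degenerate inputs are errors, not silences: empty genomes, empty
sequences, coordinates outside a chromosome, unplaced genes at
extraction, zero hits at percentage computation, and relative position
0 anywhere all raise immediately.

## Known limitations

* Genome-scale published totals for a specific species (hundreds of
  thousands of sites across tens of thousands of genes) are
  release-dependent and are not targets of the test suite.
* The homology screen's "significant alignment" is operationalized as
  the 80%/50% thresholds above; the original external-aligner settings
  behind such screens are typically unpublished.
* No position-weight-matrix scoring; consensus matching is binary by
  design, with de novo refinement delegated to external motif tools
  via the exported fragment FASTA.
* Promoter windows are fixed-length; genes with shorter intergenic
  distances will include neighbouring gene sequence.
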