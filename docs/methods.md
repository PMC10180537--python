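# Methods

This note documents the models, parameters and design choices behind
`mirseedling`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Preprocessing

Reads pass through a fixed cascade: adapter trimming → quality filter →
length filter → collapsing → ncRNA subtraction. Accounting is enforced
programmatically: the terminal categories always sum to the input read
count, and the ncRNA/clean split always covers the retained reads.

- **Adapter trimming.** The leftmost read position where a prefix of the
  3′ adapter aligns with ≥ 8 overlapping bases (`min_overlap`) and a
  mismatch rate ≤ 0.1 truncates the read. Reads with no detectable
  adapter pass through flagged `untrimmed` — short-insert libraries can
  legitimately contain full-length inserts, and the accounting reports
  both conventions.
- **Quality.** "Below Q30" is interpreted as *mean* read Phred < 30.
  Per-base thresholding would discard many short high-quality reads on
  a single bad cycle; mean-quality filtering is the common small-RNA
  practice. Reads containing `N` are discarded by default.
- **Length.** Bounds of 16–40 nt are applied to the post-trim insert,
  never the raw read.
- **ncRNA subtraction.** A tag is removed iff its sequence or reverse
  complement occurs as an *exact* substring of a reference ncRNA. No
  mismatch tolerance: exactness makes the rule reproducible and the
  false-removal rate on synthetic data identically zero.

## Conserved miRNA identification

A tag is conserved when an equal-length mature reference miRNA lies
within Hamming distance 1 (U/T unified). This implements the stated
"at most a single mismatch" homology criterion directly and
deterministically; alignment with indels and E-values are deliberately
out of scope. Ties are content-based — fewest mismatches, then
lexicographically smallest reference id — so classification is invariant
under database shuffling (verified by test). Naming strips the species
prefix (`ath-miR159a` → `cci-miR159a`); distinct tags colliding on a
local name get numeric suffixes, lowest-mismatch hit first. Conserved
tags are excluded from novel-discovery input.

## RNA folding

`fold.py` implements a **reduced nearest-neighbor model**: Turner-style
stacking energies for the 21 distinct helix steps (including G:U
wobbles), hairpin/bulge/internal loop penalties by size with
Jacobson–Stockmayer log extrapolation beyond the tables, an internal-loop
asymmetry term (0.5 kcal/mol per unpaired-count difference, capped at
3.0), and an affine multiloop cost (3.4 close + 0.4 per branch). No
dangling ends, no coaxial stacking, no special tetraloops, 37 °C only.
Pseudoknots are excluded and hairpin loops hold ≥ 3 unpaired bases.

Energies are integers in 0.01 kcal/mol units. This makes three routes
agree *exactly*, with no floating-point slack: the Zuker-type dynamic
program (numba-compiled; interior loops capped at 30 unpaired bases, the
standard bound), re-scoring of any dot-bracket by loop decomposition,
and exhaustive enumeration of all structures for sequences ≤ 25 nt (the
test oracle). Traceback prefers unpaired positions and the earliest
branch at energy ties, so folding is deterministic across platforms.

Consequence of the reduced model: absolute MFE values differ from
UNAFold/ViennaRNA outputs, so per-precursor energies of published
catalogues are *not* reproduced. All MFEI-based decisions use the index
formula (AMFE = |MFE|/L×100; MFEI = AMFE/GC%) and the published
threshold and table statistics instead. MFEI is reported as a positive
magnitude, matching catalogue convention.

## Novel miRNA discovery

Unexplained tags are exact-mapped (full length, both strands) to the
user-supplied contigs; tags with > 20 loci are treated as repetitive and
dropped. Around each locus, candidate windows extend by every
combination of the flank grid (0, 20, 50, 100, 150, 250 nt), clipped and
deduplicated — a transparent, configurable stand-in for excision
heuristics whose details are unpublished in the tools this replaces.

Each window is folded and screened, first failure recorded:

| rule | default | provenance |
|---|---|---|
| mature on a single arm (no loop overlap) | required | standard |
| paired mature bases | ≥ 14 | plant-annotation practice |
| mature/star duplex mismatches | ≤ 4 | plant-annotation practice |
| largest asymmetric bulge | ≤ 2 | plant-annotation practice |
| MFEI | ≥ 0.70 | published precursor/other-RNA discriminant |
| terminal loop | ≥ 3 nt | folding minimum |

Only the MFEI threshold is a published numeric rule; the structural
values follow common plant miRNA annotation criteria and are fully
configurable (`NovelCriteria`). Per tag the best accepted candidate wins
(highest MFEI, ties to the shortest window). Tags on opposite arms of
one hairpin (nearby mature intervals, same contig and strand) are
collapsed into a single call — the higher-count tag is the mature, the
other arm's reads become `star_read_count` — mirroring how discovery
tools report a precursor once. Calls are named `cci-miRN<k>-<arm>` in
descending read-count order; the ordering principle of published
catalogues is not stated, so this is a convention.

## Target prediction

The scoring scheme follows the published psRNATarget conventions:
mismatch 1.0, G:U wobble 0.5, gap 2.0, penalties doubled at miRNA
positions 2–13 (5′ seed), expectation cutoff 5.0, at most one gap. The
scanner evaluates every ungapped window plus single-gap variants and
keeps the best alignment per overlapping cluster, deterministically
ordered. A central non-Watson–Crick position (9–11) marks a site as
likely translational inhibition rather than cleavage — an attribute,
not a filter. Query miRNAs must have read count ≥ 5 (the copy-number
gate). Duplex MFE per site sums nearest-neighbor stacking over
consecutive paired positions of the aligned intermolecular duplex, with
no intramolecular structure; the stack table's helix-direction symmetry
makes the value invariant to which strand is read as the query.

The transcript library is a required user input: the original analyses
ran against an unnamed library for a genome-less species, so absolute
target counts are not reproducible and are not claimed.

## Network and annotation tables

Edges are deduplicated per (miRNA, transcript), keeping the
lowest-expectation site; the edge weight is the duplex MFE (more
negative = stronger), the stated basis for such networks. Annotation
category percentages use the *annotated-target* denominator (the
alternative — all targets — is not stated in the figures this emulates);
unannotated targets are reported as their own bucket over all targets.
GO assignment itself requires external databases and is out of scope:
the module consumes a pre-made annotation table.

## qPCR

Relative expression is 2^(−ΔCt) against the endogenous control (U6),
with amplification efficiency fixed at 2 (no efficiencies are published
for the assays this emulates; the base is overridable). Biological ×
technical designs collapse technical replicates first (mean per sample),
then compute statistics over biological samples — the common convention.
The spread reported is the SD of per-sample 2^(−ΔCt).

## Synthetic data

The generator defines the study conditions; its defaults emulate the
features the real library reports:

- **Tag abundances** are log-normal (μ = 2.0, σ = 1.5 on the log scale),
  giving a few high-count tags and a long tail down to counts 1–2, the
  structure visible in deep sRNA catalogues.
- **Unique-tag lengths** are drawn 16–40 nt with ~36% mass at 24 nt and
  23 > 21 > 22 next, matching the reported distribution shape.
- **Precursors** are built as arm–loop–arm hairpins: star = reverse
  complement of the mature with exactly `star_mismatches` substitutions
  (default 2; never at the duplex ends, never creating a wobble — the
  mismatch count is exact by construction). A perfect-stem precursor is
  a perfect inverted repeat whose strand is genuinely ambiguous, which
  is why the default is nonzero. Each construct is rejection-sampled
  until it folds as designed and passes the acceptance rules — planted
  precursors are true positives *by construction*, so recovery tests
  measure the pipeline (mapping, excision, folding, clustering), not
  generator luck.
- **Genomes** place precursors on random strands and shuffled
  (structure-free) decoys with ≥ 150 nt separation; star-arm reads are
  emitted at 15% of the mature count (≥ 1 read) so the duplex is always
  observable.
- **Contaminants** are random 16–40 nt slices of synthetic ncRNA decoy
  references, binomially making up the requested read fraction.
- **Planted target sites** are reverse-complement sites edited to score
  *exactly* a designed expectation under the default scheme (mismatches
  and wobbles placed non-seed first, seed if the budget demands);
  unreachable designs raise.
- Everything is bit-deterministic under a fixed seed, and truth tables
  record every planted feature and pre-error count.

What passing these tests does **not** show: robustness to sequencing
error profiles of real instruments, UMI effects, isomiR heterogeneity,
repeat-rich genomes, or incomplete/fragmented assemblies. The simulated
contigs are short and non-repetitive by design; real discoveries depend
on assembly quality in ways no synthetic test can certify.

## Problem sizes

The test suite and the reproduction script use desk-scale sizes chosen
to exercise every code path with exact oracles: 100 random sequences
(≤ 25 nt) for folding enumeration, 500 mutated tags vs a 200-entry
reference for classification, a 5-precursor / 50-decoy genome
(2 × 10 kb) for recovery, 50 random miRNA/transcript pairs for target
scanning, and 10,000 reads for count conservation.

## Known limitations

- The reduced energy model trades absolute accuracy for verifiability;
  MFEI values for real precursors will differ somewhat from
  UNAFold-derived published values (the 0.70 threshold is applied to
  this package's own energies).
- Mapping is exact-match only; SNPs or sequencing errors in reads
  suppress loci rather than mis-assigning them.
- Conserved counting is defined as "distinct tags with a qualifying
  hit". Published summaries of the same data report several different
  conserved totals depending on the counting unit; this package's
  definition is the one stated here.
- The target scanner is O(transcript × miRNA) per pair with single-gap
  variants; it is intended for transcript sets of thousands, not whole
  transcriptomes of millions of isoforms.
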