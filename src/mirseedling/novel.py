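"""Novel miRNA discovery from hairpin evidence.

Tags left unexplained by homology are exact-mapped to the supplied
reference contigs, candidate precursor windows are excised around each
locus on a fixed flank grid, folded, and screened with the acceptance
criteria: the mature must sit on one arm of a stem-loop, be well paired
against its star, and the precursor's MFEI must reach the 0.70 threshold
that separates miRNA precursors from other RNA classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .fold import (
    EnergyModel,
    SecondaryStructure,
    amfe,
    default_model,
    fold_mfe,
    gc_content,
    hairpin_features,
    mfei,
)
from .seqio import ReferenceSequence, UniqueTag, reverse_complement, to_dna, to_rna

__all__ = [
    "GenomicLocus",
    "NovelCriteria",
    "PrecursorCandidate",
    "NovelMiRNA",
    "FLANK_GRID",
    "map_tags",
    "excise_windows",
    "evaluate_candidate",
    "call_novel",
    "write_novel_table",
]

FLANK_GRID = (0, 20, 50, 100, 150, 250)


@dataclass(frozen=True)
class GenomicLocus:
    contig_id: str
    start: int   # 0-based half-open
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid locus interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class NovelCriteria:
    """Structural acceptance rules for a candidate precursor.

    The MFEI threshold of 0.70 is the published discriminator between
    miRNA precursors and other RNA classes; the remaining values follow
    standard plant miRNA annotation practice and are configurable.
    """

    min_mfei: float = 0.70
    min_paired_mature: int = 14
    max_mature_mismatches: int = 4
    max_asymmetric_bulge: int = 2
    min_terminal_loop: int = 3


@dataclass(frozen=True)
class PrecursorCandidate:
    locus: GenomicLocus
    precursor_seq: str        # RNA alphabet, strand-resolved
    structure: SecondaryStructure
    gc_percent: float
    amfe: float
    mfei: float
    mature_tag: UniqueTag
    mature_span: tuple[int, int]
    star_span: tuple[int, int]
    arm: str
    verdict: str              # "accepted" or first failed rule

    @property
    def accepted(self) -> bool:
        return self.verdict == "accepted"


@dataclass(frozen=True)
class NovelMiRNA:
    name: str                 # cci-miRN<k>-<5p|3p>
    sequence: str             # RNA alphabet
    read_count: int
    strand: str
    mfei: float
    candidate: PrecursorCandidate = field(repr=False)
    star_read_count: int = 0  # reads on the opposite arm of the same hairpin

    @property
    def length(self) -> int:
        return len(self.sequence)


def _mature_genomic_interval(cand: PrecursorCandidate) -> tuple[int, int]:
    """Plus-strand genomic interval of the mature within the window."""
    w0, w1 = cand.locus.start, cand.locus.end
    m0, m1 = cand.mature_span
    if cand.locus.strand == "+":
        return (w0 + m0, w0 + m1)
    return (w1 - m1, w1 - m0)


def map_tags(
    tags: Sequence[UniqueTag],
    contigs: Sequence[ReferenceSequence],
    max_loci: int = 20,
) -> dict[str, list[GenomicLocus]]:
    """Exact, full-length occurrences of each tag on both contig strands.

    Loci are reported in plus-strand coordinates regardless of hit strand.
    Tags occurring more than ``max_loci`` times are treated as repetitive
    and dropped (empty locus list).
    """
    out: dict[str, list[GenomicLocus]] = {}
    prepared = [(c.seq_id, to_dna(c.sequence)) for c in contigs]
    for tag in tags:
        fwd = to_dna(tag.sequence)
        rev = reverse_complement(fwd)
        loci: list[GenomicLocus] = []
        for contig_id, seq in prepared:
            for query, strand in ((fwd, "+"), (rev, "-")):
                start = seq.find(query)
                while start != -1:
                    loci.append(
                        GenomicLocus(contig_id, start, start + len(query), strand)
                    )
                    start = seq.find(query, start + 1)
        if len(loci) > max_loci:
            loci = []  # repetitive
        out[tag.sequence] = loci
    return out


def excise_windows(
    locus: GenomicLocus,
    contigs: Sequence[ReferenceSequence] | dict[str, str],
    flank_grid: Sequence[int] = FLANK_GRID,
) -> list[tuple[tuple[int, int], str]]:
    """Candidate precursor windows around a mapped locus.

    Extends the locus upstream/downstream by every combination of the
    flank grid, clips to contig bounds, deduplicates, and resolves the
    sequence to the locus strand.  Returns ``((start, end), sequence)``
    pairs in plus-strand coordinates.
    """
    if isinstance(contigs, dict):
        lookup = contigs
    else:
        lookup = {c.seq_id: to_dna(c.sequence) for c in contigs}
    seq = lookup[locus.contig_id]
    n = len(seq)
    seen: set[tuple[int, int]] = set()
    out: list[tuple[tuple[int, int], str]] = []
    for f in flank_grid:
        for g in flank_grid:
            start = max(0, locus.start - f)
            end = min(n, locus.end + g)
            if (start, end) in seen:
                continue
            seen.add((start, end))
            window = seq[start:end]
            if locus.strand == "-":
                window = reverse_complement(window)
            out.append(((start, end), window))
    out.sort(key=lambda w: (w[0][1] - w[0][0], w[0]))
    return out


def evaluate_candidate(
    window_seq: str,
    window_span: tuple[int, int],
    locus: GenomicLocus,
    tag: UniqueTag,
    model: EnergyModel | None = None,
    criteria: NovelCriteria = NovelCriteria(),
) -> PrecursorCandidate:
    """Fold one excised window and apply the acceptance rules in order.

    Rules, first failure recorded as the verdict: the mature must lie on a
    single arm (no terminal-loop overlap); enough mature bases must pair;
    the mature/star duplex may carry only limited mismatches and small
    asymmetric bulges; the precursor MFEI must be >= the threshold; and
    the hairpin must keep a terminal loop.
    """
    model = model or default_model()
    window_dna = to_dna(window_seq)
    mature = to_dna(tag.sequence)
    pos = window_dna.find(mature)
    if pos == -1:
        raise ValueError("mature tag does not occur in the window")
    span = (pos, pos + len(mature))
    structure = fold_mfe(window_dna, model)
    gc = gc_content(window_dna)
    a = amfe(structure.mfe, len(window_dna))
    m = mfei(structure.mfe, len(window_dna), gc) if gc > 0 else 0.0
    feats = hairpin_features(structure, span)

    verdict = "accepted"
    if feats.arm == "loop-spanning":
        verdict = "loop overlap"
    elif feats.paired_mature_bases < criteria.min_paired_mature:
        verdict = (
            f"paired mature bases {feats.paired_mature_bases} < "
            f"{criteria.min_paired_mature}"
        )
    elif feats.mature_mismatches > criteria.max_mature_mismatches:
        verdict = (
            f"mature/star mismatches {feats.mature_mismatches} > "
            f"{criteria.max_mature_mismatches}"
        )
    elif feats.largest_asymmetric_bulge > criteria.max_asymmetric_bulge:
        verdict = (
            f"asymmetric bulge {feats.largest_asymmetric_bulge} > "
            f"{criteria.max_asymmetric_bulge}"
        )
    elif m < criteria.min_mfei:
        verdict = f"MFEI < {criteria.min_mfei:.2f}"
    elif feats.terminal_loop_size < criteria.min_terminal_loop:
        verdict = (
            f"terminal loop {feats.terminal_loop_size} < "
            f"{criteria.min_terminal_loop}"
        )

    return PrecursorCandidate(
        locus=GenomicLocus(locus.contig_id, window_span[0], window_span[1],
                           locus.strand),
        precursor_seq=to_rna(window_dna),
        structure=structure,
        gc_percent=gc,
        amfe=a,
        mfei=m,
        mature_tag=tag,
        mature_span=span,
        star_span=feats.star_span,
        arm=feats.arm,
        verdict=verdict,
    )


def call_novel(
    tags: Sequence[UniqueTag],
    contigs: Sequence[ReferenceSequence],
    model: EnergyModel | None = None,
    criteria: NovelCriteria = NovelCriteria(),
    max_loci: int = 20,
    flank_grid: Sequence[int] = FLANK_GRID,
) -> tuple[list[NovelMiRNA], list[PrecursorCandidate]]:
    """Full discovery pass over homology-unexplained tags.

    Per tag the best accepted candidate is kept (highest MFEI, ties to the
    shortest window).  Tags landing on the two arms of the same hairpin —
    a mature/star pair, recognisable by nearby mature intervals on the
    same contig and strand — are collapsed into one call: the
    higher-count tag is the mature and the other arm's reads are recorded
    as star support.  Calls are named ``cci-miRN1...`` in order of
    descending read count (ties by sequence) with the arm suffix taken
    from the hairpin geometry.  Returns the named calls plus every
    rejected candidate (for the rejection log).
    """
    model = model or default_model()
    lookup = {c.seq_id: to_dna(c.sequence) for c in contigs}
    loci_by_tag = map_tags(tags, contigs, max_loci)
    rejected: list[PrecursorCandidate] = []
    best_by_tag: dict[str, PrecursorCandidate] = {}
    for tag in tags:
        best: PrecursorCandidate | None = None
        for locus in loci_by_tag[tag.sequence]:
            for window_span, window_seq in excise_windows(locus, lookup, flank_grid):
                cand = evaluate_candidate(
                    window_seq, window_span, locus, tag, model, criteria
                )
                if not cand.accepted:
                    rejected.append(cand)
                    continue
                key = (-cand.mfei, len(cand.precursor_seq))
                if best is None or key < (-best.mfei, len(best.precursor_seq)):
                    best = cand
        if best is not None:
            best_by_tag[tag.sequence] = best

    # collapse mature/star pairs: candidates on the same contig and strand
    # whose mature intervals fall within one hairpin's reach
    clusters: list[list[PrecursorCandidate]] = []
    for cand in sorted(
        best_by_tag.values(),
        key=lambda c: (c.locus.contig_id, c.locus.strand,
                       _mature_genomic_interval(c)),
    ):
        iv = _mature_genomic_interval(cand)
        if clusters:
            prev = clusters[-1][-1]
            piv = _mature_genomic_interval(prev)
            if (
                prev.locus.contig_id == cand.locus.contig_id
                and prev.locus.strand == cand.locus.strand
                and iv[0] - piv[1] < 60
            ):
                clusters[-1].append(cand)
                continue
        clusters.append([cand])

    picked: list[tuple[PrecursorCandidate, int]] = []
    for cluster in clusters:
        cluster.sort(key=lambda c: (-c.mature_tag.count, c.mature_tag.sequence))
        star_reads = sum(c.mature_tag.count for c in cluster[1:])
        picked.append((cluster[0], star_reads))

    picked.sort(key=lambda p: (-p[0].mature_tag.count, p[0].mature_tag.sequence))
    calls = [
        NovelMiRNA(
            name=f"cci-miRN{k}-{cand.arm}",
            sequence=to_rna(cand.mature_tag.sequence),
            read_count=cand.mature_tag.count,
            strand=cand.locus.strand,
            mfei=round(cand.mfei, 2),
            candidate=cand,
            star_read_count=star_reads,
        )
        for k, (cand, star_reads) in enumerate(picked, start=1)
    ]
    return calls, rejected


def write_novel_table(path: str | Path, calls: Iterable[NovelMiRNA]) -> None:
    """TSV mirroring the novel-miRNA catalogue columns."""
    with Path(path).open("w") as handle:
        handle.write("name\tsequence\tlength\tread_count\tstrand\tmfei_of_precursor\n")
        for c in calls:
            handle.write(
                f"{c.name}\t{c.sequence}\t{c.length}\t{c.read_count}\t"
                f"{c.strand}\t{c.mfei:.2f}\n"
            )
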