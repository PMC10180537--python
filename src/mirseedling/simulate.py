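"""Synthetic data generation with full truth bookkeeping.

Generates every input the pipeline consumes — planted stem-loop
precursors in synthetic contigs, small-RNA reads (conserved homologs,
novel mature/star arms, ncRNA contaminants, background tags, adapters,
sequencing errors), transcripts with planted complementary target sites,
and replicate Ct tables — together with truth tables recording what was
planted, so every stage can be verified against generator bookkeeping
without any external data.

The read simulator emulates the count structure seen in deep small-RNA
catalogues: per-tag abundances are drawn log-normally, giving a few
high-abundance tags and a long tail down to counts of 1-2, and unique-tag
lengths are drawn 16-40 nt with a 24-nt mode.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import (
    MatureMiRNARecord,
    ReferenceSequence,
    SmallRNARead,
    reverse_complement,
    to_dna,
)
from .targets import TargetScoringScheme, score_duplex

__all__ = [
    "PlantedPrecursor",
    "GenomeTruth",
    "ReadsTruth",
    "TranscriptomeTruth",
    "make_precursor",
    "make_genome",
    "simulate_reads",
    "make_transcriptome",
    "make_ncrna_reference",
    "make_ct_table",
]

_NTS = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float = 50.0) -> str:
    pg = gc / 200.0
    pa = (100.0 - gc) / 200.0
    return "".join(rng.choice(_NTS, size=length, p=[pa, pg, pg, pa]))


def _weighted_length(rng: np.random.Generator) -> int:
    """Tag length in [16, 40] with the characteristic 24-nt mode.

    Weights follow the shape reported for deep plant small-RNA libraries:
    ~36% of unique tags at 24 nt, then 23 > 21 > 22 nt, with a shallow
    tail over the remaining lengths.
    """
    lengths = np.arange(16, 41)
    weights = np.full(len(lengths), 2.0)
    for length, w in ((24, 36.4), (23, 8.6), (21, 6.3), (22, 5.4)):
        weights[length - 16] = w
    return int(rng.choice(lengths, p=weights / weights.sum()))


# ---------------------------------------------------------------------------
# Precursors and genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPrecursor:
    """A constructed stem-loop: mature arm, loop, star arm (plus pads)."""

    sequence: str                 # DNA alphabet, 5'->3'
    mature_span: tuple[int, int]  # half-open, within sequence
    star_span: tuple[int, int]
    arm: str                      # arm carrying the mature: "5p" | "3p"

    @property
    def mature(self) -> str:
        return self.sequence[self.mature_span[0]:self.mature_span[1]]


def make_precursor(
    mature: str,
    loop_len: int = 8,
    star_mismatches: int = 0,
    gc_target: float = 50.0,
    seed: int | np.random.Generator = 0,
    arm: str = "5p",
    pad: int = 4,
) -> PlantedPrecursor:
    """Construct a hairpin precursor around a given mature sequence.

    The star arm is the reverse complement of the mature bearing exactly
    ``star_mismatches`` substitutions (never at the two terminal bases, so
    the duplex stays anchored); the terminal loop and short pads are
    random sequence at ``gc_target`` GC%.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mature = to_dna(mature)
    if not 18 <= len(mature) <= 26:
        raise ValueError(f"mature length {len(mature)} outside [18, 26]")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    if star_mismatches > len(mature) - 4:
        raise ValueError("too many star mismatches for the mature length")
    star = list(reverse_complement(mature))
    if star_mismatches:
        positions = rng.choice(
            np.arange(2, len(star) - 2), size=star_mismatches, replace=False
        )
        for p in positions:
            # star[p] faces mature[L-1-p]; pick a base that neither
            # complements nor wobbles with it, so the mismatch is real
            facing = mature[len(mature) - 1 - p]
            comp = {"A": "T", "T": "A", "G": "C", "C": "G"}[facing]
            wobble = {"G": "T", "T": "G"}.get(facing)
            choices = [c for c in "ACGT" if c not in (comp, wobble)]
            star[p] = str(rng.choice(choices))
    star_seq = "".join(star)
    loop = _random_seq(rng, loop_len, gc_target)
    pad5 = _random_seq(rng, pad, gc_target)
    pad3 = _random_seq(rng, pad, gc_target)
    if arm == "5p":
        seq = pad5 + mature + loop + star_seq + pad3
        m0 = len(pad5)
        s0 = m0 + len(mature) + loop_len
    elif arm == "3p":
        seq = pad5 + star_seq + loop + mature + pad3
        s0 = len(pad5)
        m0 = s0 + len(star_seq) + loop_len
    else:
        raise ValueError(f"arm must be 5p or 3p, got {arm!r}")
    return PlantedPrecursor(
        sequence=seq,
        mature_span=(m0, m0 + len(mature)),
        star_span=(s0, s0 + len(star_seq)),
        arm=arm,
    )


@dataclass(frozen=True)
class PlantedLocus:
    contig_id: str
    start: int
    end: int
    strand: str
    mature: str        # the miRNA-sense sequence (DNA alphabet)
    arm: str
    kind: str          # "precursor" | "decoy"
    star: str = ""     # the star-arm sequence in precursor orientation


@dataclass
class GenomeTruth:
    contigs: list[ReferenceSequence]
    precursors: list[PlantedLocus]
    decoys: list[PlantedLocus]
    seed: int
    params: dict = field(default_factory=dict)

    def mature_tags(self) -> list[str]:
        return [p.mature for p in self.precursors]

    def write_manifest(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "params": self.params,
            "n_precursors": len(self.precursors),
            "n_decoys": len(self.decoys),
            "precursors": [vars(p) for p in self.precursors],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def make_genome(
    n_precursors: int = 5,
    n_decoys: int = 50,
    contig_len: int = 10_000,
    seed: int = 0,
    mature_len: tuple[int, int] = (21, 24),
    loop_len: int = 8,
    star_mismatches: int = 2,
    gc_target: float = 55.0,
    n_contigs: int = 2,
) -> GenomeTruth:
    """Synthetic contigs with planted precursors and structure-free decoys.

    Precursors land on random strands; decoys are shuffled precursor-like
    sequences (same composition, no designed hairpin).  The default 2 star
    mismatches mirror real duplexes and keep the hairpin from being a
    perfect inverted repeat (which would make its strand ambiguous).
    Features never overlap; infeasible packing raises.
    """
    from .novel import GenomicLocus, NovelCriteria, evaluate_candidate
    from .seqio import UniqueTag

    rng = np.random.default_rng(seed)
    criteria = NovelCriteria()
    features: list[tuple[str, str, str, str, str]] = []
    # (sequence-to-insert, strand, mature(miRNA sense), star, arm)
    for _ in range(n_precursors):
        # rejection-sample until the construct genuinely folds as designed
        # (an unlucky loop can pair with an arm end and shift the register),
        # so every planted precursor is a true positive by construction
        for _attempt in range(50):
            L = int(rng.integers(mature_len[0], mature_len[1] + 1))
            mature = _random_seq(rng, L, gc_target)
            arm = str(rng.choice(["5p", "3p"]))
            prec = make_precursor(
                mature, loop_len=loop_len, star_mismatches=star_mismatches,
                gc_target=gc_target, seed=rng, arm=arm,
            )
            cand = evaluate_candidate(
                prec.sequence,
                (0, len(prec.sequence)),
                GenomicLocus("draft", 0, len(prec.sequence), "+"),
                UniqueTag(mature, 1),
                criteria=criteria,
            )
            if cand.accepted and cand.arm == arm:
                break
        else:
            raise ValueError("could not construct an acceptable precursor")
        star = prec.sequence[prec.star_span[0]:prec.star_span[1]]
        strand = str(rng.choice(["+", "-"]))
        features.append((prec.sequence, strand, mature, star, arm))
    decoy_feats: list[str] = []
    for _ in range(n_decoys):
        L = int(rng.integers(mature_len[0], mature_len[1] + 1))
        prec = make_precursor(
            _random_seq(rng, L, gc_target), loop_len=loop_len,
            star_mismatches=0, gc_target=gc_target, seed=rng,
        )
        shuffled = "".join(rng.permutation(list(prec.sequence)))
        decoy_feats.append(shuffled)

    total_feature_len = sum(len(f[0]) for f in features) + sum(
        len(d) for d in decoy_feats
    )
    # 150-nt gaps between features plus 300-nt contig ends kept feature-free
    needed = (
        total_feature_len + 150 * (n_precursors + n_decoys) + 600 * n_contigs
    )
    if needed > contig_len * n_contigs:
        raise ValueError("features do not fit in the requested contigs")

    contig_seqs = [
        list(_random_seq(rng, contig_len, 45.0)) for _ in range(n_contigs)
    ]
    placements: list[list[tuple[int, int]]] = [[] for _ in range(n_contigs)]

    def place(length: int) -> tuple[int, int]:
        # 150-nt inter-feature gap keeps neighbouring hairpins distinguishable
        for _attempt in range(1000):
            ci = int(rng.integers(0, n_contigs))
            start = int(rng.integers(300, contig_len - length - 300))
            if all(
                start + length + 150 <= s or e + 150 <= start
                for s, e in placements[ci]
            ):
                placements[ci].append((start, start + length))
                return ci, start
        raise ValueError("could not place feature without overlap")

    precursors: list[PlantedLocus] = []
    for seq, strand, mature, star, arm in features:
        insert = seq if strand == "+" else reverse_complement(seq)
        ci, start = place(len(insert))
        contig_seqs[ci][start:start + len(insert)] = list(insert)
        precursors.append(
            PlantedLocus(
                contig_id=f"contig{ci + 1}",
                start=start,
                end=start + len(insert),
                strand=strand,
                mature=mature,
                arm=arm,
                kind="precursor",
                star=star,
            )
        )
    decoys: list[PlantedLocus] = []
    for dseq in decoy_feats:
        ci, start = place(len(dseq))
        contig_seqs[ci][start:start + len(dseq)] = list(dseq)
        decoys.append(
            PlantedLocus(
                contig_id=f"contig{ci + 1}",
                start=start,
                end=start + len(dseq),
                strand="+",
                mature="",
                arm="",
                kind="decoy",
            )
        )
    contigs = [
        ReferenceSequence(seq_id=f"contig{i + 1}", sequence="".join(s))
        for i, s in enumerate(contig_seqs)
    ]
    truth = GenomeTruth(
        contigs=contigs,
        precursors=precursors,
        decoys=decoys,
        seed=seed,
        params={
            "n_precursors": n_precursors,
            "n_decoys": n_decoys,
            "contig_len": contig_len,
            "mature_len": list(mature_len),
            "loop_len": loop_len,
            "gc_target": gc_target,
            "n_contigs": n_contigs,
        },
    )
    # planted matures must be unique exact-mappable tags
    for p in truth.precursors:
        if truth.mature_tags().count(p.mature) != 1:
            raise ValueError("duplicate planted mature sequence; use another seed")
    return truth


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

@dataclass
class ReadsTruth:
    """Pre-error per-tag read counts by category."""

    novel_mature: dict[str, int] = field(default_factory=dict)
    novel_star: dict[str, int] = field(default_factory=dict)
    conserved: dict[str, int] = field(default_factory=dict)
    ncrna: dict[str, int] = field(default_factory=dict)
    background: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    params: dict = field(default_factory=dict)

    def all_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for cat in (self.novel_mature, self.novel_star, self.conserved,
                    self.ncrna, self.background):
            for seq, c in cat.items():
                out[seq] = out.get(seq, 0) + c
        return out

    @property
    def total_reads(self) -> int:
        return sum(self.all_counts().values())


def _lognormal_count(rng: np.random.Generator, mu: float, sigma: float) -> int:
    return max(1, int(round(rng.lognormal(mu, sigma))))


def simulate_reads(
    genome_truth: GenomeTruth | None = None,
    mature_db: Sequence[MatureMiRNARecord] = (),
    ncrna_ref: Sequence[ReferenceSequence] = (),
    depth_mu: float = 2.0,
    depth_sigma: float = 1.5,
    star_fraction: float = 0.15,
    error_rate: float = 0.0,
    adapter: str = "",
    ncrna_fraction: float = 0.0,
    n_background_tags: int = 0,
    seed: int = 0,
    base_quality: int = 38,
) -> tuple[list[SmallRNARead], ReadsTruth]:
    """Emit small-RNA reads for every planted signal source.

    Per-tag abundances are log-normal(mu, sigma); star-arm reads are
    emitted at ``star_fraction`` of the mature count (at least 1, so the
    duplex is always observable).  Contaminants are random 16-40 nt slices
    of the ncRNA references making up ``ncrna_fraction`` of all reads
    (binomially); background tags are random sequences with the 24-nt
    length mode.  The adapter is appended verbatim to every read and
    substitution errors are applied at ``error_rate``; truth counts are
    recorded pre-error.
    """
    rng = np.random.default_rng(seed)
    truth = ReadsTruth(
        seed=seed,
        params={
            "depth_mu": depth_mu,
            "depth_sigma": depth_sigma,
            "star_fraction": star_fraction,
            "error_rate": error_rate,
            "adapter": adapter,
            "ncrna_fraction": ncrna_fraction,
            "n_background_tags": n_background_tags,
        },
    )
    if genome_truth is not None:
        lookup = {c.seq_id: to_dna(c.sequence) for c in genome_truth.contigs}
        for locus in genome_truth.precursors:
            count = _lognormal_count(rng, depth_mu, depth_sigma)
            truth.novel_mature[locus.mature] = (
                truth.novel_mature.get(locus.mature, 0) + count
            )
            star = locus.star or reverse_complement(locus.mature)
            star_count = max(1, int(round(count * star_fraction)))
            truth.novel_star[star] = truth.novel_star.get(star, 0) + star_count
            assert locus.mature in (
                lookup[locus.contig_id][locus.start:locus.end]
                if locus.strand == "+"
                else reverse_complement(
                    lookup[locus.contig_id][locus.start:locus.end]
                )
            )
    for rec in mature_db:
        count = _lognormal_count(rng, depth_mu, depth_sigma)
        truth.conserved[rec.sequence] = truth.conserved.get(rec.sequence, 0) + count
    for _ in range(n_background_tags):
        tag = _random_seq(rng, _weighted_length(rng), 45.0)
        count = _lognormal_count(rng, 0.3, 0.8)
        truth.background[tag] = truth.background.get(tag, 0) + count

    if ncrna_fraction > 0 and ncrna_ref:
        n_other = truth.total_reads
        total_planned = int(round(n_other / (1.0 - ncrna_fraction)))
        n_cont = int(rng.binomial(total_planned, ncrna_fraction))
        n_tags = max(1, min(50, n_cont))
        slices: list[str] = []
        for _ in range(n_tags):
            ref = ncrna_ref[int(rng.integers(0, len(ncrna_ref)))]
            refseq = to_dna(ref.sequence)
            length = min(_weighted_length(rng), len(refseq))
            start = int(rng.integers(0, len(refseq) - length + 1))
            slices.append(refseq[start:start + length])
        if n_cont > 0:
            alloc = rng.multinomial(n_cont, np.ones(n_tags) / n_tags)
            for tag, c in zip(slices, alloc):
                if c > 0:
                    truth.ncrna[tag] = truth.ncrna.get(tag, 0) + int(c)

    reads: list[SmallRNARead] = []
    serial = 0
    for category, tags in (
        ("novel", truth.novel_mature),
        ("star", truth.novel_star),
        ("cons", truth.conserved),
        ("ncrna", truth.ncrna),
        ("bg", truth.background),
    ):
        for tag, count in tags.items():
            for _ in range(count):
                seq = tag + to_dna(adapter)
                if error_rate > 0:
                    chars = list(seq)
                    for i in range(len(chars)):
                        if rng.random() < error_rate:
                            chars[i] = str(
                                rng.choice([c for c in "ACGT" if c != chars[i]])
                            )
                    seq = "".join(chars)
                serial += 1
                reads.append(
                    SmallRNARead(
                        read_id=f"read{serial}_{category}",
                        sequence=seq,
                        quality=tuple([base_quality] * len(seq)),
                    )
                )
    order = rng.permutation(len(reads))
    return [reads[i] for i in order], truth


def make_ncrna_reference(
    n_refs: int = 6, length: int = 300, seed: int = 0
) -> list[ReferenceSequence]:
    """Synthetic rRNA/tRNA/snRNA-like decoy reference sequences."""
    rng = np.random.default_rng(seed)
    kinds = ["rRNA", "tRNA", "snRNA", "snoRNA"]
    return [
        ReferenceSequence(
            seq_id=f"{kinds[i % len(kinds)]}_{i + 1}",
            sequence=_random_seq(rng, length, 52.0),
            description=f"synthetic {kinds[i % len(kinds)]} decoy",
        )
        for i in range(n_refs)
    ]


# ---------------------------------------------------------------------------
# Transcripts with planted target sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSite:
    mirna_id: str
    transcript_id: str
    start: int    # 0-based position of the site on the transcript
    end: int
    designed_expectation: float


@dataclass
class TranscriptomeTruth:
    transcripts: list[ReferenceSequence]
    sites: list[PlantedSite]
    seed: int
    params: dict = field(default_factory=dict)


def _edit_site(
    mirna: str,
    expectation: float,
    rng: np.random.Generator,
    scheme: TargetScoringScheme,
) -> str:
    """Reverse-complement site edited to score exactly ``expectation``.

    Edits are placed outside the seed region (weight 1) first — each
    mismatch adds 1.0, a wobble adds 0.5 — then inside the seed (weight 2)
    if the budget demands it.  Raises if the design value is unreachable.
    """
    m = to_dna(mirna)
    L = len(m)
    site = list(reverse_complement(m))  # site[L-1-k] faces miRNA position k+1
    budget = expectation
    if round(budget * 2) != budget * 2:
        raise ValueError("designed expectation must be a multiple of 0.5")
    nonseed = [p for p in range(1, L + 1)
               if not scheme.seed_start <= p <= scheme.seed_end]
    seedpos = [p for p in range(1, L + 1)
               if scheme.seed_start <= p <= scheme.seed_end]
    used: set[int] = set()

    def mismatch_at(p: int) -> None:
        a = m[p - 1]
        idx = L - p
        # any base that neither complements nor wobbles with a
        for b in "ACGT":
            if not _wc(a, b) and (a, b) not in (("G", "T"), ("T", "G")):
                site[idx] = b
                return
        raise AssertionError

    def wobble_at_candidates(pool: list[int]) -> int | None:
        for p in pool:
            if p in used:
                continue
            if m[p - 1] in ("G", "T"):
                return p
        return None

    def _wc(a: str, b: str) -> bool:
        return a + b in ("AT", "TA", "GC", "CG")

    # integer part first: mismatches at weight-1 positions, then weight-2
    while budget >= 1.0 - 1e-9:
        placed = False
        for p in nonseed:
            if p not in used:
                mismatch_at(p)
                used.add(p)
                budget -= 1.0
                placed = True
                break
        if placed:
            continue
        if budget >= 2.0 - 1e-9:
            for p in seedpos:
                if p not in used:
                    mismatch_at(p)
                    used.add(p)
                    budget -= 2.0
                    placed = True
                    break
        if not placed:
            break
    if budget > 1e-9:
        if abs(budget - 0.5) < 1e-9:
            p = wobble_at_candidates(nonseed)
            if p is not None:
                idx = L - p
                site[idx] = "T" if m[p - 1] == "G" else "G"
                used.add(p)
                budget = 0.0
        elif abs(budget - 1.0) < 1e-9:
            p = wobble_at_candidates(seedpos)
            if p is not None:
                idx = L - p
                site[idx] = "T" if m[p - 1] == "G" else "G"
                used.add(p)
                budget = 0.0
    if budget > 1e-9:
        raise ValueError(
            f"designed expectation {expectation} unreachable for this miRNA"
        )
    result = "".join(site)
    score, _ = score_duplex(m, result, scheme)
    if abs(score - expectation) > 1e-9:
        raise ValueError(
            f"constructed site scores {score}, wanted {expectation}"
        )
    return result


def make_transcriptome(
    n_transcripts: int = 10,
    planted_sites: Sequence[tuple[str, str, float]] = (),
    transcript_len: int = 800,
    seed: int = 0,
    scheme: TargetScoringScheme = TargetScoringScheme(),
) -> TranscriptomeTruth:
    """Random transcripts with target sites planted at designed expectation.

    ``planted_sites`` holds (mirna_id, mirna_sequence, designed
    expectation) triples; sites are spread round-robin over transcripts at
    non-overlapping random positions and each embedded site scores exactly
    its design value under the default scheme.
    """
    rng = np.random.default_rng(seed)
    seqs = [list(_random_seq(rng, transcript_len, 45.0))
            for _ in range(n_transcripts)]
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n_transcripts)]
    sites: list[PlantedSite] = []
    for k, (mirna_id, mirna_seq, design) in enumerate(planted_sites):
        site_seq = _edit_site(mirna_seq, design, rng, scheme)
        ti = k % n_transcripts
        L = len(site_seq)
        for _attempt in range(200):
            start = int(rng.integers(30, transcript_len - L - 30))
            if all(start + L + 25 <= s or e + 25 <= start
                   for s, e in occupied[ti]):
                break
        else:
            raise ValueError("could not place site without overlap")
        occupied[ti].append((start, start + L))
        seqs[ti][start:start + L] = list(site_seq)
        sites.append(
            PlantedSite(
                mirna_id=mirna_id,
                transcript_id=f"transcript{ti + 1}",
                start=start,
                end=start + L,
                designed_expectation=design,
            )
        )
    transcripts = [
        ReferenceSequence(seq_id=f"transcript{i + 1}", sequence="".join(s))
        for i, s in enumerate(seqs)
    ]
    return TranscriptomeTruth(
        transcripts=transcripts,
        sites=sites,
        seed=seed,
        params={
            "n_transcripts": n_transcripts,
            "transcript_len": transcript_len,
        },
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def make_ct_table(
    assay_counts: dict[str, int],
    n_biological: int = 6,
    n_technical: int = 3,
    reference_assay: str = "U6",
    reference_ct: float = 19.0,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format Ct table whose expression tracks given read counts.

    Each assay's true dCt against the reference is ``14 - log2(count)``,
    so higher-count miRNAs amplify earlier; per-well Gaussian noise at
    ``noise_sd`` cycles.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample in range(1, n_biological + 1):
        for tech in range(1, n_technical + 1):
            rows.append(
                {
                    "assay_id": reference_assay,
                    "sample_id": f"S{sample}",
                    "replicate": tech,
                    "ct": reference_ct + rng.normal(0, noise_sd),
                }
            )
    for assay, count in assay_counts.items():
        dct = 14.0 - np.log2(max(count, 1))
        for sample in range(1, n_biological + 1):
            bio_shift = rng.normal(0, noise_sd)
            for tech in range(1, n_technical + 1):
                rows.append(
                    {
                        "assay_id": assay,
                        "sample_id": f"S{sample}",
                        "replicate": tech,
                        "ct": reference_ct + dct + bio_shift
                        + rng.normal(0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)
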