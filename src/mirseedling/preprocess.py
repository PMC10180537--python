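"""Small-RNA read preprocessing.

The filtering cascade applied to raw reads before miRNA calling:
3' adapter trimming, mean-quality filter (Q30), length bounds (16-40 nt),
collapse to unique tags, and subtraction of tags matching other ncRNA
classes (rRNA/tRNA/snRNA/snoRNA).  Produces a read-accounting table and a
unique-tag length distribution.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seqio import (
    ReferenceSequence,
    SmallRNARead,
    UniqueTag,
    collapse_reads,
    reverse_complement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "ReadAccounting",
    "LengthDistribution",
    "TrimResult",
    "trim_adapter",
    "quality_filter",
    "subtract_ncrna",
    "length_histogram",
    "run_preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Thresholds of the preprocessing cascade.

    Defaults follow the study conditions: reads below mean Q30 are removed
    and only inserts of 16-40 nt are retained.
    """

    adapter_3p: str = ""
    min_overlap: int = 8
    max_adapter_mismatch_rate: float = 0.1
    min_mean_quality: float = 30.0
    min_len: int = 16
    max_len: int = 40
    discard_n: bool = True

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not 0.0 <= self.max_adapter_mismatch_rate <= 1.0:
            raise ValueError("max_adapter_mismatch_rate must be in [0, 1]")


@dataclass(frozen=True)
class TrimResult:
    read: SmallRNARead
    status: str  # "trimmed" | "untrimmed" | "removed: empty after trim"

    @property
    def removed(self) -> bool:
        return self.status.startswith("removed")


@dataclass
class ReadAccounting:
    """Per-category read tallies; terminal categories partition the input."""

    total_reads: int = 0
    trimmed_reads: int = 0          # reads in which an adapter was found
    removed_empty: int = 0          # adapter at position 0 -> no insert
    removed_quality: int = 0
    removed_length: int = 0
    retained_reads: int = 0         # survivors entering collapsing
    ncrna_reads: int = 0            # retained reads whose tag matched ncRNA
    clean_reads: int = 0            # retained reads surviving ncRNA subtraction
    unique_tags: int = 0
    ncrna_unique_tags: int = 0
    clean_unique_tags: int = 0

    def check_conservation(self) -> None:
        terminal = (
            self.removed_empty + self.removed_quality
            + self.removed_length + self.retained_reads
        )
        if terminal != self.total_reads:
            raise AssertionError(
                f"accounting leak: {terminal} != total {self.total_reads}"
            )
        if self.ncrna_reads + self.clean_reads != self.retained_reads:
            raise AssertionError("ncRNA partition does not cover retained reads")

    def as_rows(self) -> list[tuple[str, int]]:
        return [
            ("total_reads", self.total_reads),
            ("trimmed_reads", self.trimmed_reads),
            ("removed_empty_after_trim", self.removed_empty),
            ("removed_low_quality", self.removed_quality),
            ("removed_length", self.removed_length),
            ("retained_reads", self.retained_reads),
            ("ncrna_reads", self.ncrna_reads),
            ("clean_reads", self.clean_reads),
            ("unique_tags", self.unique_tags),
            ("ncrna_unique_tags", self.ncrna_unique_tags),
            ("clean_unique_tags", self.clean_unique_tags),
        ]


@dataclass
class LengthDistribution:
    """Unique-tag counts per length with percentages on the unique-tag basis."""

    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[int, float]:
        n = self.total
        if n == 0:
            return {}
        return {length: 100.0 * c / n for length, c in sorted(self.counts.items())}

    @property
    def mode(self) -> int | None:
        if not self.counts:
            return None
        # highest count; ties resolved toward the shorter length
        return min(self.counts, key=lambda k: (-self.counts[k], k))

    def as_rows(self) -> list[tuple[int, int, float]]:
        pct = self.percentages
        return [(k, self.counts[k], round(pct[k], 2)) for k in sorted(self.counts)]


def trim_adapter(read: SmallRNARead, cfg: PreprocessConfig) -> TrimResult:
    """Locate and cut the 3' adapter.

    Scans for the leftmost read position where a prefix of the adapter
    aligns to the read's 3' end with at least ``min_overlap`` overlapping
    bases and a mismatch rate at most ``max_adapter_mismatch_rate``; the
    read (and its qualities) is truncated there.  Reads with no detectable
    adapter pass through flagged ``"untrimmed"`` — they may be full-length
    inserts.
    """
    adapter = cfg.adapter_3p
    if not adapter:
        return TrimResult(read, "untrimmed")
    seq = read.sequence
    n, m = len(seq), len(adapter)
    for start in range(0, n - cfg.min_overlap + 1):
        overlap = min(n - start, m)
        if overlap < cfg.min_overlap:
            break
        mismatches = sum(
            1 for k in range(overlap) if seq[start + k] != adapter[k]
        )
        if mismatches / overlap <= cfg.max_adapter_mismatch_rate:
            if start == 0:
                return TrimResult(read, "removed: empty after trim")
            trimmed = SmallRNARead(
                read_id=read.read_id,
                sequence=seq[:start],
                quality=read.quality[:start],
            )
            return TrimResult(trimmed, "trimmed")
    return TrimResult(read, "untrimmed")


def quality_filter(read: SmallRNARead, cfg: PreprocessConfig) -> bool:
    """Keep iff mean Phred >= threshold and (optionally) no N present."""
    if read.mean_quality < cfg.min_mean_quality:
        return False
    if cfg.discard_n and "N" in read.sequence:
        return False
    return True


def subtract_ncrna(
    tags: Sequence[UniqueTag],
    ncrna_ref: Sequence[ReferenceSequence],
) -> tuple[list[UniqueTag], list[UniqueTag]]:
    """Partition tags into (retained, removed) by exact ncRNA substring match.

    A tag is removed iff its sequence, or its reverse complement, occurs as
    an exact substring of any reference sequence.  No mismatches are
    tolerated — the rule is deliberately exact and reproducible.
    """
    if not ncrna_ref:
        logger.warning("empty ncRNA reference: no tags subtracted")
        return list(tags), []
    refs = [r.sequence.upper().replace("U", "T") for r in ncrna_ref]
    retained: list[UniqueTag] = []
    removed: list[UniqueTag] = []
    for tag in tags:
        rc = reverse_complement(tag.sequence)
        hit = any(tag.sequence in ref or rc in ref for ref in refs)
        (removed if hit else retained).append(tag)
    return retained, removed


def length_histogram(tags: Iterable[UniqueTag]) -> LengthDistribution:
    """Unique-tag length distribution (each distinct sequence counts once)."""
    counts = Counter(t.length for t in tags)
    return LengthDistribution(counts=dict(counts))


def run_preprocess(
    reads: Iterable[SmallRNARead],
    cfg: PreprocessConfig,
    ncrna_ref: Sequence[ReferenceSequence] = (),
) -> tuple[list[UniqueTag], ReadAccounting, LengthDistribution]:
    """Full cascade: trim -> quality -> length -> collapse -> ncRNA subtraction.

    The length filter is applied to the post-trim insert, never the raw
    read.  Returns the clean tag set, the accounting table (which always
    conserves the input read count) and the clean-tag length distribution.
    """
    acc = ReadAccounting()
    survivors: list[SmallRNARead] = []
    for read in reads:
        acc.total_reads += 1
        tr = trim_adapter(read, cfg)
        if tr.removed:
            acc.trimmed_reads += 1
            acc.removed_empty += 1
            continue
        if tr.status == "trimmed":
            acc.trimmed_reads += 1
        read = tr.read
        if not quality_filter(read, cfg):
            acc.removed_quality += 1
            continue
        if not (cfg.min_len <= len(read.sequence) <= cfg.max_len):
            acc.removed_length += 1
            continue
        acc.retained_reads += 1
        survivors.append(read)

    tags = collapse_reads(survivors)
    acc.unique_tags = len(tags)
    clean, ncrna = subtract_ncrna(tags, ncrna_ref)
    acc.ncrna_unique_tags = len(ncrna)
    acc.clean_unique_tags = len(clean)
    acc.ncrna_reads = sum(t.count for t in ncrna)
    acc.clean_reads = sum(t.count for t in clean)
    acc.check_conservation()
    return clean, acc, length_histogram(clean)
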