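"""Sequence I/O and read collapsing.

Reads and writes the formats the pipeline touches (FASTA, Phred+33 FASTQ,
tag tables) and collapses raw small-RNA reads into counted unique tags —
the unit every downstream stage works with.  The internal alphabet is DNA
(``U`` is converted to ``T`` on ingest); mature-miRNA outputs are reported
back in RNA alphabet.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SmallRNARead",
    "UniqueTag",
    "ReferenceSequence",
    "MatureMiRNARecord",
    "ParseError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_mature_fasta",
    "collapse_reads",
    "parse_mirbase_id",
    "reverse_complement",
    "to_rna",
    "to_dna",
    "write_tag_table",
    "read_tag_table",
]

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")
_VALID_NT = frozenset("ACGTUN")


class ParseError(ValueError):
    """Malformed sequence file."""


def to_dna(sequence: str) -> str:
    """Uppercase and convert RNA to the internal DNA alphabet (U -> T)."""
    return sequence.upper().replace("U", "T")


def to_rna(sequence: str) -> str:
    """Convert an internal DNA-alphabet sequence to RNA (T -> U)."""
    return sequence.upper().replace("T", "U")


def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,U,N}; U is treated as T.

    An involution on DNA-alphabet input: ``rc(rc(s)) == s``.
    """
    s = sequence.upper()
    bad = set(s) - _VALID_NT
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SmallRNARead:
    """A single sequenced small-RNA read with per-base Phred qualities."""

    read_id: str
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    @property
    def mean_quality(self) -> float:
        if not self.quality:
            return 0.0
        return sum(self.quality) / len(self.quality)


@dataclass(frozen=True)
class UniqueTag:
    """A collapsed distinct read sequence with its total read count."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"tag count must be >= 1, got {self.count}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceSequence:
    seq_id: str
    sequence: str
    description: str = ""


@dataclass(frozen=True)
class MatureMiRNARecord:
    """A mature miRNA reference entry with a miRBase-style identifier."""

    mirbase_id: str
    sequence: str  # internal DNA alphabet
    species_prefix: str = field(default="")
    family: str = field(default="")
    arm: str = field(default="unknown")  # one of {"5p", "3p", "unknown"}

    @classmethod
    def from_id(cls, mirbase_id: str, sequence: str) -> "MatureMiRNARecord":
        prefix, family, arm = parse_mirbase_id(mirbase_id)
        return cls(
            mirbase_id=mirbase_id,
            sequence=to_dna(sequence),
            species_prefix=prefix,
            family=family,
            arm=arm,
        )

    @property
    def local_name(self) -> str:
        """Identifier with the species prefix removed (``miR156d-3p``)."""
        parts = self.mirbase_id.split("-", 1)
        return parts[1] if len(parts) == 2 else self.mirbase_id


_MIRBASE_RE = re.compile(
    r"^(?P<prefix>[a-zA-Z]{3,4})-(?:miR|MIR|mir)(?P<num>\d+)"
    r"(?P<variant>[a-zA-Z]*)(?P<rest>(?:[._-][\w.]+)*)$"
)


def parse_mirbase_id(mirbase_id: str) -> tuple[str, str, str]:
    """Split a miRBase-style id into (species prefix, family, arm).

    ``stu-miR156d-3p`` -> ``("stu", "MIR156", "3p")``;
    ``ppt-miR894`` -> ``("ppt", "MIR894", "unknown")``.
    Unparseable ids yield family ``"NA"`` (mirroring catalogue rows whose
    family could not be assigned) rather than raising.
    """
    m = _MIRBASE_RE.match(mirbase_id.strip())
    if not m:
        return ("", "NA", "unknown")
    arm = "unknown"
    rest = m.group("rest").lower()
    if rest.endswith("-5p") or rest.endswith(".5p"):
        arm = "5p"
    elif rest.endswith("-3p") or rest.endswith(".3p"):
        arm = "3p"
    return (m.group("prefix"), "MIR" + m.group("num"), arm)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[SmallRNARead]:
    """Yield reads from a Phred+33 FASTQ file in file order.

    Sequences are uppercased and U is converted to T.  Malformed records
    (truncated file, quality/sequence length mismatch) raise
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    with path.open() as handle:
        record_no = 0
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                record_no += 1
                yield SmallRNARead(
                    read_id=rec.id,
                    sequence=to_dna(str(rec.seq)),
                    quality=tuple(rec.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:
            line = record_no * 4 + 1
            raise ParseError(
                f"{path}: malformed FASTQ near line {line} "
                f"(record {record_no + 1}): {exc}"
            ) from exc


def write_fastq(path: str | Path, reads: Iterable[SmallRNARead]) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quality)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read a (possibly line-wrapped) FASTA file.

    Header order is preserved; duplicate ids raise :class:`ParseError`.
    """
    path = Path(path)
    out: list[ReferenceSequence] = []
    seen: set[str] = set()
    with path.open() as handle:
        first = handle.read(1)
        if first and first not in (">", ";", "\n"):
            raise ParseError(f"{path}: sequence data before first FASTA header")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip()
            out.append(
                ReferenceSequence(
                    seq_id=rec.id,
                    sequence=str(rec.seq).upper(),
                    description=desc,
                )
            )
    return out


def write_fasta(path: str | Path, records: Iterable[ReferenceSequence],
                width: int = 70) -> None:
    with Path(path).open("w") as handle:
        for rec in records:
            header = rec.seq_id
            if rec.description:
                header += f" {rec.description}"
            handle.write(f">{header}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


def read_mature_fasta(path: str | Path) -> list[MatureMiRNARecord]:
    """Read a mature miRNA reference FASTA (headers are miRBase-style ids)."""
    return [
        MatureMiRNARecord.from_id(rec.seq_id, rec.sequence)
        for rec in read_fasta(path)
    ]


# ---------------------------------------------------------------------------
# Tag collapsing and tag tables
# ---------------------------------------------------------------------------

def collapse_reads(reads: Iterable[SmallRNARead | str]) -> list[UniqueTag]:
    """Collapse reads into unique tags with occurrence counts.

    Accepts reads or bare sequences.  The result is sorted by descending
    count, ties broken by lexicographic sequence, so downstream reports are
    deterministic.  Total count is conserved: ``sum(t.count) == len(reads)``.
    """
    counts: dict[str, int] = {}
    for r in reads:
        seq = r if isinstance(r, str) else r.sequence
        counts[seq] = counts.get(seq, 0) + 1
    return [
        UniqueTag(sequence=s, count=c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def write_tag_table(path: str | Path, tags: Iterable[UniqueTag]) -> None:
    with Path(path).open("w") as handle:
        handle.write("sequence\tlength\tcount\n")
        for t in tags:
            handle.write(f"{t.sequence}\t{t.length}\t{t.count}\n")


def read_tag_table(path: str | Path) -> list[UniqueTag]:
    tags: list[UniqueTag] = []
    with Path(path).open() as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:3] != ["sequence", "length", "count"]:
            raise ParseError(f"{path}: unexpected tag-table header {header}")
        for line in handle:
            seq, _length, count = line.rstrip("\n").split("\t")
            tags.append(UniqueTag(sequence=seq, count=int(count)))
    return tags
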