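"""Conserved miRNA classification.

A unique tag is called a conserved miRNA when it matches a known mature
plant miRNA of the same length with at most one substitution (equal-length
Hamming matching; U and T are unified before comparison).  Hits receive a
species-local ``cci-`` name and are summarised per miRNA family.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import MatureMiRNARecord, UniqueTag, to_dna, to_rna

__all__ = [
    "ConservedHit",
    "FamilySummary",
    "hamming",
    "match_conserved",
    "classify_tags",
    "assign_names",
    "summarize_families",
    "write_conserved_table",
]


@dataclass(frozen=True)
class ConservedHit:
    tag: UniqueTag
    reference: MatureMiRNARecord
    mismatches: int
    assigned_name: str = ""

    @property
    def family(self) -> str:
        return self.reference.family

    @property
    def read_count(self) -> int:
        return self.tag.count


@dataclass(frozen=True)
class FamilySummary:
    family: str
    member_count: int
    total_read_count: int


def hamming(a: str, b: str) -> int:
    """Substitution count between equal-length sequences (U unified with T)."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    a = to_dna(a)
    b = to_dna(b)
    return sum(1 for x, y in zip(a, b) if x != y)


def match_conserved(
    tag: UniqueTag,
    db: Sequence[MatureMiRNARecord],
    max_mismatches: int = 1,
) -> ConservedHit | None:
    """Best equal-length reference within the mismatch budget, or None.

    Among qualifying references the hit with fewest mismatches wins; ties
    are broken by lexicographically smallest miRBase id, so classification
    is invariant under shuffling of the reference database.
    """
    best: tuple[int, str, MatureMiRNARecord] | None = None
    tag_seq = to_dna(tag.sequence)
    for ref in db:
        if len(ref.sequence) != len(tag_seq):
            continue
        d = hamming(tag_seq, ref.sequence)
        if d > max_mismatches:
            continue
        key = (d, ref.mirbase_id)
        if best is None or key < (best[0], best[1]):
            best = (d, ref.mirbase_id, ref)
    if best is None:
        return None
    return ConservedHit(tag=tag, reference=best[2], mismatches=best[0])


def classify_tags(
    tags: Iterable[UniqueTag],
    db: Sequence[MatureMiRNARecord],
    max_mismatches: int = 1,
) -> tuple[list[ConservedHit], list[UniqueTag]]:
    """Split tags into named conserved hits and the unexplained remainder.

    The remainder is the input to novel-miRNA discovery: a tag explained by
    homology is never also offered as a novel candidate.
    """
    hits: list[ConservedHit] = []
    remainder: list[UniqueTag] = []
    for tag in tags:
        hit = match_conserved(tag, db, max_mismatches)
        if hit is None:
            remainder.append(tag)
        else:
            hits.append(hit)
    return assign_names(hits), remainder


def assign_names(hits: Sequence[ConservedHit]) -> list[ConservedHit]:
    """Attach ``cci-`` names derived from the matched reference.

    The assigned name is ``cci-`` plus the reference id minus its species
    prefix.  When distinct tags map to references sharing a local name
    (e.g. the same miRNA from two species), the lowest-mismatch tag keeps
    the plain name and later ones get a numeric disambiguating suffix.
    """
    ordered = sorted(
        hits, key=lambda h: (h.mismatches, h.reference.mirbase_id, h.tag.sequence)
    )
    used: dict[str, int] = {}
    named: list[ConservedHit] = []
    for hit in ordered:
        base = "cci-" + hit.reference.local_name
        n = used.get(base, 0)
        used[base] = n + 1
        name = base if n == 0 else f"{base}.{n + 1}"
        named.append(replace(hit, assigned_name=name))
    return named


def summarize_families(hits: Sequence[ConservedHit]) -> list[FamilySummary]:
    """One row per family: distinct-tag member count and summed read count.

    Sorted by member count descending, ties by family label.
    """
    members: dict[str, set[str]] = defaultdict(set)
    reads: dict[str, int] = defaultdict(int)
    for hit in hits:
        members[hit.family].add(hit.tag.sequence)
        reads[hit.family] += hit.read_count
    rows = [
        FamilySummary(
            family=fam, member_count=len(members[fam]), total_read_count=reads[fam]
        )
        for fam in members
    ]
    rows.sort(key=lambda r: (-r.member_count, r.family))
    return rows


def write_conserved_table(path: str | Path, hits: Sequence[ConservedHit]) -> None:
    """TSV of conserved hits, sequences in RNA alphabet, sorted by read count."""
    rows = sorted(hits, key=lambda h: (-h.read_count, h.assigned_name))
    with Path(path).open("w") as handle:
        handle.write(
            "assigned_name\tsequence\tlength\treference_mirna\tfamily\t"
            "mismatches\tread_count\n"
        )
        for h in rows:
            handle.write(
                f"{h.assigned_name}\t{to_rna(h.tag.sequence)}\t{h.tag.length}\t"
                f"{h.reference.mirbase_id}\t{h.family}\t{h.mismatches}\t"
                f"{h.read_count}\n"
            )
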