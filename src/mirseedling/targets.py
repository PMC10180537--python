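"""Plant miRNA target prediction.

Scores miRNA/transcript complementarity with a position-weighted penalty
scheme of the kind used by plant target predictors: each aligned position
contributes 0 for a Watson-Crick pair, 0.5 for a G:U wobble, 1 for a
mismatch and 2 for a gap, with penalties doubled inside the seed region
(miRNA positions 2-13 from the 5' end).  Sites with total expectation at
or below the cutoff (default 5.0) are reported.  Query miRNAs are gated
on read copy number (>= 5 by default) before scanning.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .fold import EnergyModel, _PTYPE, default_model, encode
from .seqio import ReferenceSequence, to_dna

__all__ = [
    "TargetScoringScheme",
    "TargetSite",
    "filter_queries",
    "score_duplex",
    "scan_transcript",
    "scan_all",
    "duplex_mfe",
    "write_site_table",
]

_WOBBLE = {("G", "T"), ("T", "G")}  # internal DNA alphabet: U == T


def _complement(a: str, b: str) -> bool:
    return a + b in ("AT", "TA", "GC", "CG")


@dataclass(frozen=True)
class TargetScoringScheme:
    mismatch_penalty: float = 1.0
    wobble_penalty: float = 0.5
    gap_penalty: float = 2.0
    seed_start: int = 2            # 1-based, from miRNA 5' end, inclusive
    seed_end: int = 13
    seed_multiplier: float = 2.0
    expectation_cutoff: float = 5.0
    max_gaps: int = 1

    def position_weight(self, pos_1based: int) -> float:
        if self.seed_start <= pos_1based <= self.seed_end:
            return self.seed_multiplier
        return 1.0


@dataclass(frozen=True)
class TargetSite:
    """One predicted miRNA binding site on a transcript.

    ``start``/``end`` are 1-based inclusive transcript coordinates.  The
    pattern string runs 5'->3' along the miRNA: ``|`` Watson-Crick pair,
    ``o`` G:U wobble, ``x`` mismatch, ``-`` gap.  ``inhibition`` marks
    likely translational inhibition (a non-WC position anywhere in the
    central positions 9-11), the alternative being cleavage.
    """

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    expectation: float
    duplex_mfe: float
    pattern: str
    inhibition: bool


def filter_queries(entries: Sequence, min_copies: int = 5) -> list:
    """Keep query miRNAs/tags whose read count is >= ``min_copies``.

    Accepts anything exposing ``count`` or ``read_count``.
    """
    kept = []
    for e in entries:
        count = getattr(e, "count", None)
        if count is None:
            count = getattr(e, "read_count")
        if count >= min_copies:
            kept.append(e)
    return kept


def score_duplex(
    mirna: str,
    site: str,
    scheme: TargetScoringScheme = TargetScoringScheme(),
) -> tuple[float, str]:
    """Expectation of an ungapped antiparallel miRNA/site alignment.

    ``site`` is the transcript window 5'->3'; miRNA position 1 (5' end)
    faces the 3' end of the site.  Returns (expectation, pattern).
    """
    if not mirna or not site:
        raise ValueError("empty sequence")
    m = to_dna(mirna)
    s = to_dna(site)
    if len(m) != len(s):
        raise ValueError("ungapped scoring requires equal lengths")
    total = 0.0
    pattern = []
    for k in range(len(m)):
        a = m[k]
        b = s[len(s) - 1 - k]  # antiparallel
        if _complement(a, b):
            pattern.append("|")
            continue
        w = scheme.position_weight(k + 1)
        if (a, b) in _WOBBLE:
            total += scheme.wobble_penalty * w
            pattern.append("o")
        else:
            total += scheme.mismatch_penalty * w
            pattern.append("x")
    return total, "".join(pattern)


def _score_gapped(m: str, s: str, gap_strand: str, gap_pos: int,
                  scheme: TargetScoringScheme) -> tuple[float, str]:
    """One-gap alignment: a gap inserted in the miRNA (site base unpaired)
    or in the site (miRNA base unpaired) at miRNA-coordinate ``gap_pos``."""
    total = 0.0
    pattern = []
    mi = 0
    si = len(s) - 1
    pos = 1  # miRNA 1-based position counter (gap occupies a position too)
    while mi < len(m) or si >= 0:
        if pos == gap_pos:
            w = scheme.position_weight(pos)
            total += scheme.gap_penalty * w
            pattern.append("-")
            if gap_strand == "mirna":
                si -= 1   # site base faces a gap
            else:
                mi += 1   # miRNA base faces a gap
            pos += 1
            continue
        if mi >= len(m) or si < 0:
            break
        a, b = m[mi], s[si]
        if _complement(a, b):
            pattern.append("|")
        else:
            w = scheme.position_weight(pos)
            if (a, b) in _WOBBLE:
                total += scheme.wobble_penalty * w
                pattern.append("o")
            else:
                total += scheme.mismatch_penalty * w
                pattern.append("x")
        mi += 1
        si -= 1
        pos += 1
    return total, "".join(pattern)


def _central_non_wc(pattern: str) -> bool:
    central = pattern[8:11]  # miRNA positions 9-11
    return any(c != "|" for c in central)


def scan_transcript(
    mirna_id: str,
    mirna: str,
    transcript: ReferenceSequence,
    scheme: TargetScoringScheme = TargetScoringScheme(),
    model: EnergyModel | None = None,
) -> list[TargetSite]:
    """All qualifying binding sites of one miRNA on one transcript.

    Evaluates every ungapped window plus single-gap variants, keeps
    alignments with expectation <= cutoff, and reduces overlapping
    candidates to the best per cluster (lowest expectation, ties to the
    leftmost start).  Output is ordered by transcript position.
    """
    model = model or default_model()
    m = to_dna(mirna)
    t = to_dna(transcript.sequence)
    n, L = len(t), len(m)
    if n < L:
        return []
    raw: list[tuple[float, int, int, str]] = []  # (exp, start0, end0, pattern)
    for start in range(0, n - L + 1):
        window = t[start:start + L]
        e, pat = score_duplex(m, window, scheme)
        if e <= scheme.expectation_cutoff:
            raw.append((e, start, start + L, pat))
        if scheme.max_gaps >= 1:
            # gap in miRNA: site window one base longer
            if start + L + 1 <= n:
                wlong = t[start:start + L + 1]
                for gp in range(1, L + 2):
                    e, pat = _score_gapped(m, wlong, "mirna", gp, scheme)
                    if e <= scheme.expectation_cutoff:
                        raw.append((e, start, start + L + 1, pat))
            # gap in site: window one base shorter
            if L - 1 > 0:
                wshort = t[start:start + L - 1]
                for gp in range(1, L + 1):
                    e, pat = _score_gapped(m, wshort, "site", gp, scheme)
                    if e <= scheme.expectation_cutoff:
                        raw.append((e, start, start + L - 1, pat))
    # best per overlapping cluster
    raw.sort(key=lambda r: (r[1], r[0], r[2]))
    sites: list[TargetSite] = []
    chosen: list[tuple[float, int, int, str]] = []
    for rec in raw:
        overlapping = [c for c in chosen if rec[1] < c[2] and c[1] < rec[2]]
        if overlapping:
            best = min(overlapping, key=lambda c: (c[0], c[1]))
            if rec[0] < best[0]:
                chosen = [c for c in chosen if c not in overlapping]
            else:
                continue
        chosen.append(rec)
    chosen.sort(key=lambda r: (r[1], r[2]))
    for e, s0, e0, pat in chosen:
        site_seq = t[s0:e0]
        dmfe = duplex_mfe(m, site_seq, model)
        sites.append(
            TargetSite(
                mirna_id=mirna_id,
                transcript_id=transcript.seq_id,
                start=s0 + 1,
                end=e0,
                expectation=e,
                duplex_mfe=dmfe,
                pattern=pat,
                inhibition=_central_non_wc(pat),
            )
        )
    return sites


def scan_all(
    queries: Sequence[tuple[str, str]],
    transcripts: Sequence[ReferenceSequence],
    scheme: TargetScoringScheme = TargetScoringScheme(),
    model: EnergyModel | None = None,
) -> list[TargetSite]:
    """Scan every (mirna_id, sequence) query against every transcript."""
    model = model or default_model()
    out: list[TargetSite] = []
    for mirna_id, seq in queries:
        for tr in transcripts:
            out.extend(scan_transcript(mirna_id, seq, tr, scheme, model))
    out.sort(key=lambda s: (s.mirna_id, s.transcript_id, s.start))
    return out


def duplex_mfe(
    mirna: str, site_seq: str, model: EnergyModel | None = None
) -> float:
    """Stacking energy of the intermolecular miRNA/site duplex (kcal/mol).

    The miRNA is paired antiparallel against the site; consecutive
    complementary or wobble pairs contribute their nearest-neighbor
    stacking energy, everything else contributes zero.  No intramolecular
    structure is considered.  Result is <= 0.
    """
    model = model or default_model()
    m = encode(to_dna(mirna))
    s = encode(to_dna(site_seq))[::-1]  # antiparallel
    L = min(len(m), len(s))
    total = 0
    for k in range(L - 1):
        p = _PTYPE[m[k], s[k]]
        q = _PTYPE[m[k + 1], s[k + 1]]
        if p > 0 and q > 0:
            e = int(model.stack[p, q])
            if e < 10 ** 7:
                total += e
    return min(total, 0) / 100.0


def write_site_table(path: str | Path, sites: Iterable[TargetSite]) -> None:
    with Path(path).open("w") as handle:
        handle.write(
            "mirna\ttranscript\tstart\tend\texpectation\tduplex_mfe\t"
            "pattern\tmode\n"
        )
        for s in sites:
            mode = "inhibition" if s.inhibition else "cleavage"
            handle.write(
                f"{s.mirna_id}\t{s.transcript_id}\t{s.start}\t{s.end}\t"
                f"{s.expectation:.2f}\t{s.duplex_mfe:.2f}\t{s.pattern}\t{mode}\n"
            )
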