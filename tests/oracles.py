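"""Independent brute-force oracles used by the test suite.

Each oracle searches its problem space exhaustively and naively, sharing
only the model *definition* (the energy function, the penalty scheme) with
the implementation under test — never its search strategy.
"""

from __future__ import annotations

from mirseedling.conserved import hamming
from mirseedling.fold import _PTYPE, encode, energy_of_structure
from mirseedling.seqio import to_dna


def enumerate_pair_sets(seq: str):
    """Yield every non-crossing set of allowed pairs (min hairpin loop 3)."""
    codes = encode(seq)
    n = len(codes)

    def rec(i: int, j: int):
        if j - i < 4:
            yield []
            return
        for rest in rec(i + 1, j):
            yield rest
        for k in range(i + 4, j + 1):
            if _PTYPE[codes[i], codes[k]] > 0:
                for inside in rec(i + 1, k - 1):
                    for after in rec(k + 1, j):
                        yield [(i, k)] + inside + after

    yield from rec(0, n - 1)


def oracle_min_energy(seq: str, model=None) -> float:
    """Exhaustive-enumeration MFE: score every structure, keep the minimum."""
    best = 0.0
    for pair_list in enumerate_pair_sets(seq):
        db = ["."] * len(seq)
        for a, b in pair_list:
            db[a], db[b] = "(", ")"
        e = energy_of_structure(seq, "".join(db), model)
        best = min(best, e)
    return best


def brute_force_nearest(tag_seq: str, db, max_mismatches: int = 1):
    """All-pairs nearest-reference search (the conserved-match oracle).

    Returns (reference, distance) or None, with the same documented
    tie-break (fewest mismatches, then smallest miRBase id).
    """
    candidates = []
    t = to_dna(tag_seq)
    for ref in db:
        if len(ref.sequence) == len(t):
            d = hamming(t, ref.sequence)
            if d <= max_mismatches:
                candidates.append((d, ref.mirbase_id, ref))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1]))
    d, _, ref = candidates[0]
    return ref, d


def oracle_scan_ungapped(mirna: str, transcript_seq: str, scheme):
    """Brute-force ungapped window enumeration with naive scoring.

    Scores every window position-by-position with an explicit complement
    table, applies the expectation cutoff, then reduces overlapping
    qualifying windows to the best one (lowest expectation, leftmost).
    Returns a list of (start_1based, end_1based, expectation).
    """
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    wob = {("G", "T"), ("T", "G")}
    m = to_dna(mirna)
    t = to_dna(transcript_seq)
    L = len(m)
    hits = []
    for start in range(len(t) - L + 1):
        window = t[start:start + L]
        total = 0.0
        for pos in range(1, L + 1):
            a = m[pos - 1]
            b = window[L - pos]
            if comp[a] == b:
                continue
            w = 2.0 if scheme.seed_start <= pos <= scheme.seed_end else 1.0
            total += (0.5 if (a, b) in wob else 1.0) * w
        if total <= scheme.expectation_cutoff:
            hits.append((total, start, start + L))
    hits.sort(key=lambda h: (h[1], h[0]))
    chosen = []
    for h in hits:
        overlapping = [c for c in chosen if h[1] < c[2] and c[1] < h[2]]
        if overlapping:
            best = min(overlapping, key=lambda c: (c[0], c[1]))
            if h[0] < best[0]:
                chosen = [c for c in chosen if c not in overlapping]
            else:
                continue
        chosen.append(h)
    return sorted((s + 1, e, exp) for exp, s, e in chosen)
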