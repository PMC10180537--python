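"""Target prediction: scoring scheme, scan vs brute force, duplex MFE."""

import random

import pytest

from mirseedling.fold import default_model
from mirseedling.seqio import ReferenceSequence, UniqueTag, reverse_complement
from mirseedling.simulate import make_transcriptome
from mirseedling.targets import (
    TargetScoringScheme,
    duplex_mfe,
    filter_queries,
    scan_transcript,
    score_duplex,
)
from mirseedling.tables import load_novel_catalogue
from oracles import oracle_scan_ungapped

MIRNA = "TGACAGAAGAGAGTGAGCACA"  # 21 nt


class TestFilterQueries:
    def test_boundary_inclusive(self):
        tags = [UniqueTag("A" * 20, 5), UniqueTag("C" * 20, 4), UniqueTag("G" * 20, 6)]
        kept = filter_queries(tags, min_copies=5)
        assert [t.count for t in kept] == [5, 6]

    def test_all_below_cutoff(self):
        assert filter_queries([UniqueTag("A" * 20, 1)], 5) == []

    def test_catalogue_copy_number_gate(self):
        """Applying the copy-number >= 5 gate to the published novel
        catalogue: only the read-count 2 and 3 entries drop out."""
        df = load_novel_catalogue()
        kept = int((df["read_count"] >= 5).sum())
        assert kept == 37
        assert sorted(df.loc[df["read_count"] < 5, "read_count"]) == [2, 3]


class TestScoreDuplex:
    def test_perfect_complement_zero(self):
        site = reverse_complement(MIRNA)
        e, pattern = score_duplex(MIRNA, site)
        assert e == 0.0
        assert pattern == "|" * 21

    def test_seed_doubling(self):
        site = list(reverse_complement(MIRNA))
        # mismatch at miRNA position 15 (non-seed): weight 1
        site15 = site[:]
        site15[21 - 15] = _mismatch_base(MIRNA[14])
        assert score_duplex(MIRNA, "".join(site15))[0] == pytest.approx(1.0)
        # same mismatch at position 3 (seed): weight 2
        site3 = site[:]
        site3[21 - 3] = _mismatch_base(MIRNA[2])
        assert score_duplex(MIRNA, "".join(site3))[0] == pytest.approx(2.0)

    def test_wobble_half_penalty(self):
        mirna = "TGACAGAAGAGAGTGAGCACA"
        site = list(reverse_complement(mirna))
        # position 15 is G: G:T wobble costs 0.5 outside the seed
        assert mirna[14] == "G"
        site[21 - 15] = "T"
        e, pattern = score_duplex(mirna, "".join(site))
        assert e == pytest.approx(0.5)
        assert pattern[14] == "o"

    def test_monotone_in_mismatches(self):
        site = list(reverse_complement(MIRNA))
        prev = 0.0
        for pos in (14, 15, 16):
            site[21 - (pos + 1)] = _mismatch_base(MIRNA[pos])
            e, _ = score_duplex(MIRNA, "".join(site))
            assert e > prev
            prev = e

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            score_duplex("", "")


def _mismatch_base(a: str) -> str:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}[a]
    wob = {"G": "T", "T": "G"}.get(a)
    return next(c for c in "ACGT" if c not in (comp, wob, a))


class TestScanTranscript:
    def test_planted_perfect_site_found(self):
        site = reverse_complement(MIRNA)
        seq = "A" * 50 + site + "A" * 50
        tr = ReferenceSequence("t1", seq)
        sites = scan_transcript("q", MIRNA, tr)
        exact = [s for s in sites if s.expectation == 0.0]
        assert len(exact) == 1
        assert exact[0].start == 51
        assert exact[0].end == 71

    def test_cutoff_boundary_excludes(self):
        scheme = TargetScoringScheme(expectation_cutoff=5.0, max_gaps=0)
        site = list(reverse_complement(MIRNA))
        # three non-seed mismatches (3.0) + one seed mismatch (2.0) = 5.0 kept;
        # one more non-seed pushes to 5.5 -> dropped
        for pos in (15, 16, 17):
            site[21 - pos] = _mismatch_base(MIRNA[pos - 1])
        site[21 - 3] = _mismatch_base(MIRNA[2])
        seq = "G" * 40 + "".join(site) + "G" * 40
        sites = scan_transcript("q", MIRNA, ReferenceSequence("t", seq), scheme)
        assert any(s.expectation == pytest.approx(5.0) for s in sites)
        site[21 - 18] = _mismatch_base(MIRNA[17])
        seq2 = "G" * 40 + "".join(site) + "G" * 40
        sites2 = scan_transcript("q", MIRNA, ReferenceSequence("t", seq2), scheme)
        assert all(s.expectation <= 5.0 for s in sites2)

    def test_matches_brute_force_enumeration(self):
        """Ungapped scan equals naive window enumeration on random pairs."""
        rng = random.Random(77)
        scheme = TargetScoringScheme(max_gaps=0)
        disagreements = 0
        for _ in range(50):
            L = rng.randint(20, 23)
            mirna = "".join(rng.choice("ACGT") for _ in range(L))
            # transcript containing a degraded site so hits actually occur
            site = list(reverse_complement(mirna))
            for _ in range(rng.randint(0, 4)):
                p = rng.randrange(L)
                site[p] = rng.choice("ACGT")
            t = (
                "".join(rng.choice("ACGT") for _ in range(rng.randint(60, 120)))
                + "".join(site)
                + "".join(rng.choice("ACGT") for _ in range(rng.randint(60, 120)))
            )
            tr = ReferenceSequence("t", t)
            got = [
                (s.start, s.end, s.expectation)
                for s in scan_transcript("q", mirna, tr, scheme)
            ]
            expected = oracle_scan_ungapped(mirna, t, scheme)
            disagreements += got != [
                (s, e, pytest.approx(x)) for s, e, x in expected
            ]
        assert disagreements == 0

    def test_gapped_variant_never_beats_perfect(self):
        site = reverse_complement(MIRNA)
        seq = "C" * 30 + site + "C" * 30
        sites = scan_transcript("q", MIRNA, ReferenceSequence("t", seq))
        best = min(s.expectation for s in sites)
        assert best == 0.0

    def test_designed_expectation_sites_score_exactly(self):
        """Generator-planted sites score exactly their design value."""
        queries = [
            ("q0", MIRNA, 0.0),
            ("q1", MIRNA, 1.0),
            ("q2", MIRNA, 2.5),
            ("q3", "TTTGGATTGAAGGGAGCTCTA", 3.0),
        ]
        truth = make_transcriptome(
            n_transcripts=4,
            planted_sites=[(q, s, e) for q, s, e in queries],
            seed=55,
        )
        by_id = {t.seq_id: t for t in truth.transcripts}
        for planted in truth.sites:
            mirna_seq = dict((q, s) for q, s, _ in queries)[planted.mirna_id]
            sites = scan_transcript(
                planted.mirna_id, mirna_seq, by_id[planted.transcript_id]
            )
            at_site = [
                s for s in sites
                if s.start == planted.start + 1 and s.end == planted.end
            ]
            assert len(at_site) == 1
            assert at_site[0].expectation == pytest.approx(
                planted.designed_expectation
            )

    def test_design_above_cutoff_not_reported(self):
        truth = make_transcriptome(
            n_transcripts=1,
            planted_sites=[("q", MIRNA, 6.0)],
            seed=56,
        )
        (tr,) = truth.transcripts
        scheme = TargetScoringScheme(expectation_cutoff=5.0)
        sites = scan_transcript("q", MIRNA, tr, scheme)
        planted = truth.sites[0]
        assert not any(
            s.start == planted.start + 1 and s.end == planted.end for s in sites
        )


class TestDuplexMfe:
    def test_perfect_complement_equals_stack_sum(self):
        model = default_model()
        from mirseedling.fold import _PTYPE, encode

        site = reverse_complement(MIRNA)
        m = encode(MIRNA)
        s = encode(site)[::-1]
        expected = 0
        for k in range(20):
            expected += int(model.stack[_PTYPE[m[k], s[k]], _PTYPE[m[k + 1], s[k + 1]]])
        assert duplex_mfe(MIRNA, site) == pytest.approx(expected / 100.0)
        assert duplex_mfe(MIRNA, site) < 0

    def test_no_pairs_zero(self):
        assert duplex_mfe("AAAAAAAAAA", "AAAAAAAAAA") == 0.0

    def test_strand_swap_symmetry(self):
        """Reading the duplex from the other strand (site as the query,
        miRNA as the site) leaves the energy unchanged — the stack table's
        helix-direction symmetry."""
        site = reverse_complement(MIRNA)
        assert duplex_mfe(MIRNA, site) == pytest.approx(duplex_mfe(site, MIRNA))
        degraded = site[:10] + "A" + site[11:]
        assert duplex_mfe(MIRNA, degraded) == pytest.approx(
            duplex_mfe(degraded, MIRNA)
        )
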