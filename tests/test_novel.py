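"""Novel discovery: mapping, excision, candidate evaluation, recovery."""

import pytest

from mirseedling.novel import (
    FLANK_GRID,
    GenomicLocus,
    NovelCriteria,
    call_novel,
    evaluate_candidate,
    excise_windows,
    map_tags,
)
from mirseedling.seqio import ReferenceSequence, UniqueTag, reverse_complement
from mirseedling.simulate import make_genome, make_precursor


@pytest.fixture(scope="module")
def small_truth():
    return make_genome(n_precursors=3, n_decoys=10, contig_len=6000, seed=21)


class TestMapTags:
    def test_minus_strand_hit(self):
        tag = UniqueTag("TGACAGAAGAGAGTGAGCACA", 1)
        contig = ReferenceSequence(
            "c1", "A" * 30 + reverse_complement(tag.sequence) + "A" * 30
        )
        loci = map_tags([tag], [contig])[tag.sequence]
        assert len(loci) == 1
        assert loci[0].strand == "-"
        assert loci[0].start == 30

    def test_absent_tag_empty(self):
        tag = UniqueTag("TGACAGAAGAGAGTGAGCACA", 1)
        contig = ReferenceSequence("c1", "A" * 80)
        assert map_tags([tag], [contig])[tag.sequence] == []

    def test_repetitive_tag_dropped(self):
        tag = UniqueTag("ACGTACGTACGTACGTACGT", 1)
        contig = ReferenceSequence("c1", ("ACGTACGTACGTACGTACGT" + "TT") * 30)
        assert map_tags([tag], [contig], max_loci=20)[tag.sequence] == []

    def test_planted_loci_match_truth(self, small_truth):
        tags = [UniqueTag(p.mature, 1) for p in small_truth.precursors]
        loci = map_tags(tags, small_truth.contigs)
        for p in small_truth.precursors:
            hits = loci[p.mature]
            assert len(hits) == 1
            (hit,) = hits
            assert hit.contig_id == p.contig_id
            assert hit.strand == p.strand
            assert p.start <= hit.start and hit.end <= p.end


class TestExciseWindows:
    def test_interior_locus_window_count(self):
        contig = {"c1": "A" * 2000}
        locus = GenomicLocus("c1", 1000, 1022, "+")
        windows = excise_windows(locus, contig)
        assert len(windows) == len(FLANK_GRID) ** 2  # no clipping collisions
        spans = {span for span, _ in windows}
        assert (1000, 1022) in spans
        assert (750, 1272) in spans

    def test_near_start_clipped_not_error(self):
        contig = {"c1": "A" * 500}
        locus = GenomicLocus("c1", 30, 52, "+")
        windows = excise_windows(locus, contig)
        assert all(span[0] >= 0 for span, _ in windows)
        assert any(span[0] == 0 for span, _ in windows)

    def test_minus_strand_sequence_reverse_complemented(self):
        seq = "ACGTTTGGCCAAGGTTCCAAGGTTCCGGAA"
        contig = {"c1": seq}
        locus = GenomicLocus("c1", 5, 25, "-")
        windows = excise_windows(locus, contig, flank_grid=(0,))
        ((span, wseq),) = windows
        assert wseq == reverse_complement(seq[5:25])


class TestEvaluateCandidate:
    def _candidate(self, criteria=NovelCriteria(), star_mismatches=0, pad=20):
        prec = make_precursor(
            "GCTGTCATCTCATGCATTTGGT", loop_len=8,
            star_mismatches=star_mismatches, seed=33, pad=pad,
        )
        tag = UniqueTag(prec.mature, 10)
        locus = GenomicLocus("c1", 0, len(prec.sequence), "+")
        return evaluate_candidate(
            prec.sequence, (0, len(prec.sequence)), locus, tag,
            criteria=criteria,
        )

    def test_ideal_hairpin_accepted(self):
        cand = self._candidate()
        assert cand.accepted
        assert cand.mfei >= 0.70
        assert cand.arm == "5p"

    def test_mfei_threshold_rejection_reason(self):
        cand = self._candidate(criteria=NovelCriteria(min_mfei=5.0))
        assert not cand.accepted
        assert "MFEI" in cand.verdict

    def test_excess_star_mismatches_rejected(self):
        cand = self._candidate(star_mismatches=8)
        assert not cand.accepted

    def test_tag_missing_from_window_raises(self):
        tag = UniqueTag("TTTTTTTTTTTTTTTTTTTTT", 1)
        locus = GenomicLocus("c1", 0, 30, "+")
        with pytest.raises(ValueError):
            evaluate_candidate("ACGT" * 10, (0, 40), locus, tag)

    def test_mfei_monotonicity(self):
        """Raising the MFEI threshold never yields more acceptances."""
        lo = self._candidate(criteria=NovelCriteria(min_mfei=0.5))
        hi = self._candidate(criteria=NovelCriteria(min_mfei=1.8))
        assert int(hi.accepted) <= int(lo.accepted)


class TestCallNovel:
    def test_empty_tag_set(self, small_truth):
        calls, rejected = call_novel([], small_truth.contigs)
        assert calls == [] and rejected == []

    def test_verdicts_recheck_consistently(self, scenario):
        crit = NovelCriteria()
        for call in scenario.novel_calls:
            cand = call.candidate
            assert cand.accepted
            assert cand.mfei >= crit.min_mfei
            feats_span = cand.mature_span
            assert cand.precursor_seq.replace("U", "T")[
                feats_span[0]:feats_span[1]
            ] == cand.mature_tag.sequence

    def test_planted_recovery_with_strands_and_arms(self, scenario):
        """Noise-free synthetic genome: every planted precursor is called,
        with the planted strand and arm, and nothing else is."""
        truth = {
            p.mature: (p.strand, p.arm)
            for p in scenario.genome_truth.precursors
        }
        called = {c.candidate.mature_tag.sequence: c for c in scenario.novel_calls}
        assert set(called) == set(truth)
        for mature, (strand, arm) in truth.items():
            call = called[mature]
            assert call.strand == strand
            assert call.candidate.arm == arm
            assert call.name.endswith(arm)

    def test_names_ordered_by_read_count(self, scenario):
        counts = [c.read_count for c in scenario.novel_calls]
        assert counts == sorted(counts, reverse=True)
        assert scenario.novel_calls[0].name.startswith("cci-miRN1-")

    def test_star_reads_collapsed_into_call(self, scenario):
        truth = scenario.reads_truth
        star_by_mature = {}
        for p in scenario.genome_truth.precursors:
            star_by_mature[p.mature] = truth.novel_star.get(p.star, 0)
        for c in scenario.novel_calls:
            mature = c.candidate.mature_tag.sequence
            assert c.star_read_count == star_by_mature[mature]
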