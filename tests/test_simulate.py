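"""Generator determinism and truth bookkeeping."""

import pytest

from mirseedling.novel import GenomicLocus, evaluate_candidate
from mirseedling.seqio import UniqueTag, reverse_complement
from mirseedling.simulate import (
    make_ct_table,
    make_genome,
    make_ncrna_reference,
    make_precursor,
    make_transcriptome,
    simulate_reads,
)


class TestMakePrecursor:
    def test_deterministic_under_seed(self):
        a = make_precursor("GCTGTCATCTCATGCATTTGGT", seed=5)
        b = make_precursor("GCTGTCATCTCATGCATTTGGT", seed=5)
        assert a == b

    def test_spans_consistent(self):
        p = make_precursor("GCTGTCATCTCATGCATTTGGT", seed=1, arm="3p")
        assert p.mature == "GCTGTCATCTCATGCATTTGGT"
        s0, s1 = p.star_span
        assert s1 - s0 == len(p.mature)
        assert p.mature_span[0] > p.star_span[0]  # 3p arm lies downstream

    def test_perfect_stem_accepted_by_default_criteria(self):
        p = make_precursor("GCTGTCATCTCATGCATTTGGT", star_mismatches=0, seed=2)
        tag = UniqueTag(p.mature, 5)
        locus = GenomicLocus("c", 0, len(p.sequence), "+")
        cand = evaluate_candidate(p.sequence, (0, len(p.sequence)), locus, tag)
        assert cand.accepted

    def test_heavily_mismatched_star_rejected(self):
        p = make_precursor("GCTGTCATCTCATGCATTTGGT", star_mismatches=8, seed=2)
        tag = UniqueTag(p.mature, 5)
        locus = GenomicLocus("c", 0, len(p.sequence), "+")
        cand = evaluate_candidate(p.sequence, (0, len(p.sequence)), locus, tag)
        assert not cand.accepted

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            make_precursor("ACGT", seed=0)  # mature too short
        with pytest.raises(ValueError):
            make_precursor("GCTGTCATCTCATGCATTTGGT", loop_len=2, seed=0)


class TestMakeGenome:
    def test_truth_table_bookkeeping(self):
        truth = make_genome(n_precursors=3, n_decoys=10, contig_len=6000, seed=4)
        assert len(truth.precursors) == 3
        assert len(truth.decoys) == 10
        # features disjoint per contig
        by_contig = {}
        for f in truth.precursors + truth.decoys:
            by_contig.setdefault(f.contig_id, []).append((f.start, f.end))
        for spans in by_contig.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_planted_sequence_present_on_stated_strand(self):
        truth = make_genome(n_precursors=3, n_decoys=5, contig_len=6000, seed=8)
        contigs = {c.seq_id: c.sequence for c in truth.contigs}
        for p in truth.precursors:
            window = contigs[p.contig_id][p.start:p.end]
            if p.strand == "-":
                window = reverse_complement(window)
            assert p.mature in window
            assert p.star in window

    def test_zero_precursors_decoy_only(self):
        truth = make_genome(n_precursors=0, n_decoys=5, contig_len=5000, seed=1)
        assert truth.precursors == [] and len(truth.decoys) == 5

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError):
            make_genome(n_precursors=50, n_decoys=50, contig_len=1000, seed=0)

    def test_deterministic(self):
        a = make_genome(n_precursors=2, n_decoys=4, contig_len=5000, seed=9)
        b = make_genome(n_precursors=2, n_decoys=4, contig_len=5000, seed=9)
        assert [c.sequence for c in a.contigs] == [c.sequence for c in b.contigs]


class TestSimulateReads:
    def test_empty_truth_no_reads(self):
        reads, truth = simulate_reads(None, seed=0)
        assert reads == [] and truth.total_reads == 0

    def test_counts_conserved_and_deterministic(self):
        genome = make_genome(n_precursors=2, n_decoys=2, contig_len=5000, seed=14)
        r1, t1 = simulate_reads(genome, seed=15, n_background_tags=10)
        r2, t2 = simulate_reads(genome, seed=15, n_background_tags=10)
        assert [r.sequence for r in r1] == [r.sequence for r in r2]
        assert len(r1) == t1.total_reads

    def test_ncrna_fraction_binomial(self):
        genome = make_genome(n_precursors=2, n_decoys=2, contig_len=5000, seed=14)
        ncrna = make_ncrna_reference(seed=1)
        _, truth = simulate_reads(
            genome, ncrna_ref=ncrna, ncrna_fraction=0.2,
            n_background_tags=200, depth_mu=3.0, seed=3,
        )
        n_other = truth.total_reads - sum(truth.ncrna.values())
        frac = sum(truth.ncrna.values()) / truth.total_reads
        assert 0.12 < frac < 0.28  # ~Binomial(n, 0.2) at this depth

    def test_adapter_on_every_read(self):
        genome = make_genome(n_precursors=2, n_decoys=2, contig_len=5000, seed=14)
        reads, _ = simulate_reads(genome, adapter="AGATCGGAAG", seed=5)
        assert all(r.sequence.endswith("AGATCGGAAG") for r in reads)

    def test_error_rate_perturbs_reads(self):
        genome = make_genome(n_precursors=3, n_decoys=2, contig_len=6000, seed=14)
        clean, truth_c = simulate_reads(genome, depth_mu=4.0, seed=6)
        noisy, truth_n = simulate_reads(genome, depth_mu=4.0, error_rate=0.05, seed=6)
        assert truth_c.all_counts() == truth_n.all_counts()  # truth is pre-error
        diffs = sum(
            a.sequence != b.sequence for a, b in zip(clean, noisy)
        )
        assert diffs > 0


class TestMakeTranscriptome:
    def test_deterministic(self):
        a = make_transcriptome(3, [("q", "TGACAGAAGAGAGTGAGCACA", 1.0)], seed=2)
        b = make_transcriptome(3, [("q", "TGACAGAAGAGAGTGAGCACA", 1.0)], seed=2)
        assert [t.sequence for t in a.transcripts] == [
            t.sequence for t in b.transcripts
        ]

    def test_unreachable_design_raises(self):
        with pytest.raises(ValueError):
            make_transcriptome(1, [("q", "TGACAGAAGAGAGTGAGCACA", 0.25)], seed=0)


class TestMakeCtTable:
    def test_shape_and_determinism(self):
        t1 = make_ct_table({"m1": 100, "m2": 10}, n_biological=6, n_technical=3, seed=1)
        t2 = make_ct_table({"m1": 100, "m2": 10}, n_biological=6, n_technical=3, seed=1)
        assert t1.equals(t2)
        assert len(t1) == 3 * 6 * 3  # U6 + 2 assays, 6 bio x 3 tech
        assert set(t1["assay_id"]) == {"U6", "m1", "m2"}
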