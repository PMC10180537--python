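"""Preprocessing cascade: trimming, filters, subtraction, accounting."""

import pytest

from mirseedling.preprocess import (
    PreprocessConfig,
    length_histogram,
    quality_filter,
    run_preprocess,
    subtract_ncrna,
    trim_adapter,
)
from mirseedling.seqio import ReferenceSequence, SmallRNARead, UniqueTag

ADAPTER = "AGATCGGAAGAGCACACGTCT"
INSERT = "TGACAGAAGAGAGTGAGCACA"


def read_of(seq: str, q: int = 38, rid: str = "r") -> SmallRNARead:
    return SmallRNARead(rid, seq, tuple([q] * len(seq)))


class TestTrimAdapter:
    def test_full_adapter_recovers_insert(self):
        cfg = PreprocessConfig(adapter_3p=ADAPTER)
        result = trim_adapter(read_of(INSERT + ADAPTER), cfg)
        assert result.status == "trimmed"
        assert result.read.sequence == INSERT
        assert len(result.read.quality) == len(INSERT)

    def test_adapter_at_start_removes_read(self):
        cfg = PreprocessConfig(adapter_3p=ADAPTER)
        result = trim_adapter(read_of(ADAPTER + "ACG"), cfg)
        assert result.removed
        assert "empty after trim" in result.status

    def test_partial_adapter_at_end_trimmed(self):
        cfg = PreprocessConfig(adapter_3p=ADAPTER, min_overlap=8)
        result = trim_adapter(read_of(INSERT + ADAPTER[:8]), cfg)
        assert result.status == "trimmed"
        assert result.read.sequence == INSERT

    def test_overlap_below_minimum_passes_untrimmed(self):
        cfg = PreprocessConfig(adapter_3p=ADAPTER, min_overlap=8)
        result = trim_adapter(read_of(INSERT + ADAPTER[:7]), cfg)
        assert result.status == "untrimmed"
        assert result.read.sequence == INSERT + ADAPTER[:7]

    def test_one_mismatch_within_rate_tolerated(self):
        mutated = "C" + ADAPTER[1:]  # 1 mismatch over 21 bases < 10%
        cfg = PreprocessConfig(adapter_3p=ADAPTER)
        result = trim_adapter(read_of(INSERT + mutated), cfg)
        assert result.status == "trimmed"
        assert result.read.sequence == INSERT


class TestQualityFilter:
    def test_boundary_mean_quality(self):
        cfg = PreprocessConfig()
        assert quality_filter(read_of("ACGT" * 5, q=40), cfg)
        assert quality_filter(read_of("ACGT" * 5, q=30), cfg)
        assert not quality_filter(read_of("ACGT" * 5, q=29), cfg)

    def test_n_discarded_when_configured(self):
        cfg = PreprocessConfig(discard_n=True)
        assert not quality_filter(read_of("ACGNACGTACGT", q=35), cfg)
        cfg2 = PreprocessConfig(discard_n=False)
        assert quality_filter(read_of("ACGNACGTACGT", q=35), cfg2)


class TestSubtractNcrna:
    TRNA = ReferenceSequence("tRNA_1", "GCGGATTTAGCTCAGTTGGGAGAGCGCCAGACTGAAGA")

    def test_exact_slice_removed(self):
        tag = UniqueTag(self.TRNA.sequence[5:26], 3)
        retained, removed = subtract_ncrna([tag], [self.TRNA])
        assert removed == [tag] and retained == []

    def test_reverse_complement_slice_removed(self):
        from mirseedling.seqio import reverse_complement

        tag = UniqueTag(reverse_complement(self.TRNA.sequence[5:26]), 1)
        retained, removed = subtract_ncrna([tag], [self.TRNA])
        assert removed == [tag]

    def test_single_mismatch_retained(self):
        slice21 = self.TRNA.sequence[5:26]
        mutated = ("A" if slice21[10] != "A" else "C")
        tag = UniqueTag(slice21[:10] + mutated + slice21[11:], 2)
        retained, removed = subtract_ncrna([tag], [self.TRNA])
        assert retained == [tag] and removed == []

    def test_empty_reference_retains_everything(self):
        tag = UniqueTag("ACGTACGTACGTACGTA", 1)
        retained, removed = subtract_ncrna([tag], [])
        assert retained == [tag] and removed == []


class TestLengthHistogram:
    def test_mode_and_percentages(self):
        tags = [UniqueTag("A" * L, 1) for L in (21, 21, 24, 24, 24)]
        # distinct sequences required: vary content
        tags = [
            UniqueTag("A" * 21, 1), UniqueTag("C" * 21, 1),
            UniqueTag("A" * 24, 1), UniqueTag("C" * 24, 1), UniqueTag("G" * 24, 1),
        ]
        dist = length_histogram(tags)
        assert dist.mode == 24
        assert dist.percentages[24] == pytest.approx(60.0)
        assert sum(dist.percentages.values()) == pytest.approx(100.0)

    def test_single_tag(self):
        dist = length_histogram([UniqueTag("ACGTACGTACGTACGTACGTA", 7)])
        assert dist.mode == 21
        assert dist.percentages == {21: 100.0}

    def test_empty(self):
        dist = length_histogram([])
        assert dist.mode is None
        assert dist.percentages == {}


class TestRunPreprocess:
    def test_empty_input_all_zero(self):
        tags, acc, dist = run_preprocess([], PreprocessConfig(adapter_3p=ADAPTER))
        assert tags == [] and acc.total_reads == 0 and dist.mode is None

    def test_no_adapter_reads_flow_through(self):
        reads = [read_of(INSERT, rid=f"r{i}") for i in range(4)]
        tags, acc, _ = run_preprocess(reads, PreprocessConfig(adapter_3p=ADAPTER))
        assert acc.trimmed_reads == 0
        assert acc.retained_reads == 4
        assert tags == [UniqueTag(INSERT, 4)]

    def test_length_filter_applies_post_trim(self):
        # 50-nt raw read whose insert is 21 nt: must be retained
        reads = [read_of(INSERT + ADAPTER + "ACGTACGT")]
        tags, acc, _ = run_preprocess(reads, PreprocessConfig(adapter_3p=ADAPTER))
        assert acc.retained_reads == 1
        assert tags[0].sequence == INSERT

    def test_accounting_conserves_reads_on_simulation(self, scenario):
        acc = scenario.accounting
        assert (
            acc.removed_empty + acc.removed_quality + acc.removed_length
            + acc.retained_reads
            == acc.total_reads
        )
        assert acc.ncrna_reads + acc.clean_reads == acc.retained_reads
        assert acc.total_reads == len(scenario.reads)

    def test_simulated_counts_recovered_exactly(self, scenario):
        """Zero-error simulation: collapsing recovers the truth counts."""
        observed = {t.sequence: t.count for t in scenario.clean_tags}
        truth = scenario.reads_truth
        expected = {}
        for cat in (truth.novel_mature, truth.novel_star,
                    truth.conserved, truth.background):
            for seq, c in cat.items():
                expected[seq] = expected.get(seq, 0) + c
        assert observed == expected

    def test_all_planted_contaminants_subtracted(self, scenario):
        observed = {t.sequence for t in scenario.clean_tags}
        for contaminant in scenario.reads_truth.ncrna:
            assert contaminant not in observed

    def test_length_mode_recovered(self, scenario):
        assert scenario.lengths.mode == 24
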