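"""Shared fixtures: one synthetic study scenario built once per session."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from mirseedling.conserved import classify_tags
from mirseedling.novel import call_novel
from mirseedling.preprocess import PreprocessConfig, run_preprocess
from mirseedling.seqio import MatureMiRNARecord
from mirseedling.simulate import (
    make_genome,
    make_ncrna_reference,
    simulate_reads,
)

ADAPTER = "AGATCGGAAGAGCACACGTCT"

MATURE_DB = [
    MatureMiRNARecord.from_id("stu-miR156d-3p", "GCUCUCUAUGCUUCUGUCAUCA"),
    MatureMiRNARecord.from_id("ath-miR159a", "UUUGGAUUGAAGGGAGCUCUA"),
    MatureMiRNARecord.from_id("mtr-miR166c", "UCGGACCAGGCUUCAUUCCUC"),
    MatureMiRNARecord.from_id("ptc-miR396f", "UUCCACGGCUUUCUUGAACUG"),
    MatureMiRNARecord.from_id("ath-miR393a-5p", "UCCAAAGGGAUCGCAUUGAUCC"),
    MatureMiRNARecord.from_id("ppt-miR894", "CGUUUCACGUCGGGUUCACC"),
]


@dataclass
class Scenario:
    genome_truth: object
    ncrna: list
    reads: list
    reads_truth: object
    clean_tags: list
    accounting: object
    lengths: object
    conserved_hits: list
    unexplained: list
    novel_calls: list
    rejected: list


@pytest.fixture(scope="session")
def scenario() -> Scenario:
    """Fixed-seed study scenario: 5 planted precursors among 50 decoys,
    conserved homolog reads, ncRNA contaminants, background tags, adapters
    on every read, zero sequencing error."""
    genome_truth = make_genome(n_precursors=5, n_decoys=50, seed=11)
    ncrna = make_ncrna_reference(seed=12)
    reads, reads_truth = simulate_reads(
        genome_truth,
        mature_db=MATURE_DB,
        ncrna_ref=ncrna,
        adapter=ADAPTER,
        ncrna_fraction=0.15,
        n_background_tags=80,
        error_rate=0.0,
        seed=13,
    )
    cfg = PreprocessConfig(adapter_3p=ADAPTER)
    clean_tags, accounting, lengths = run_preprocess(reads, cfg, ncrna)
    hits, unexplained = classify_tags(clean_tags, MATURE_DB)
    calls, rejected = call_novel(unexplained, genome_truth.contigs)
    return Scenario(
        genome_truth=genome_truth,
        ncrna=ncrna,
        reads=reads,
        reads_truth=reads_truth,
        clean_tags=clean_tags,
        accounting=accounting,
        lengths=lengths,
        conserved_hits=hits,
        unexplained=unexplained,
        novel_calls=calls,
        rejected=rejected,
    )
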