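#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds a fixed-seed scenario emulating a deep cumin-style small-RNA
experiment without external data: two contigs carrying 5 planted stem-loop
precursors among 50 structure-free decoys, a small mature-miRNA reference,
ncRNA decoy references, adapter-bearing reads (conserved homologs, novel
mature/star arms, ~15% ncRNA contaminants, background tags with the 24-nt
length mode), transcripts with planted target sites, and a replicate Ct
table.  Everything lands under results/data/ together with truth manifests.
"""

from pathlib import Path

from mirseedling.seqio import ReferenceSequence, write_fasta, write_fastq
from mirseedling.simulate import (
    make_ct_table,
    make_genome,
    make_ncrna_reference,
    make_transcriptome,
    simulate_reads,
)

SEED = 11
ADAPTER = "AGATCGGAAGAGCACACGTCT"

MATURE_REFERENCE = [
    ("stu-miR156d-3p", "GCUCUCUAUGCUUCUGUCAUCA"),
    ("ath-miR159a", "UUUGGAUUGAAGGGAGCUCUA"),
    ("mtr-miR166c", "UCGGACCAGGCUUCAUUCCUC"),
    ("ptc-miR396f", "UUCCACGGCUUUCUUGAACUG"),
    ("ath-miR393a-5p", "UCCAAAGGGAUCGCAUUGAUCC"),
    ("ppt-miR894", "CGUUUCACGUCGGGUUCACC"),
]


def main() -> None:
    out = Path("results/data")
    out.mkdir(parents=True, exist_ok=True)

    from mirseedling.seqio import MatureMiRNARecord

    mature_db = [MatureMiRNARecord.from_id(i, s) for i, s in MATURE_REFERENCE]

    genome = make_genome(n_precursors=5, n_decoys=50, seed=SEED)
    ncrna = make_ncrna_reference(seed=SEED + 1)
    reads, reads_truth = simulate_reads(
        genome, mature_db=mature_db, ncrna_ref=ncrna, adapter=ADAPTER,
        ncrna_fraction=0.15, n_background_tags=80, error_rate=0.0,
        seed=SEED + 2,
    )
    queries = [(f"planted_q{i}", p.mature) for i, p in enumerate(genome.precursors)]
    transcriptome = make_transcriptome(
        n_transcripts=8,
        planted_sites=[(q, seq, float(i % 3)) for i, (q, seq) in enumerate(queries)],
        transcript_len=600,
        seed=SEED + 3,
    )
    ct = make_ct_table(
        {"cci-miR156a-5p": 14927, "cci-miR159a": 177734, "cci-miRN1-3p": 41},
        seed=SEED + 4,
    )

    write_fasta(out / "contigs.fa", genome.contigs)
    write_fasta(out / "ncrna.fa", ncrna)
    write_fasta(
        out / "mature_reference.fa",
        [ReferenceSequence(m.mirbase_id, m.sequence) for m in mature_db],
    )
    write_fasta(out / "transcripts.fa", transcriptome.transcripts)
    write_fastq(out / "reads.fq", reads)
    ct.to_csv(out / "ct_table.tsv", sep="\t", index=False)
    genome.write_manifest(out / "genome_truth.json")

    print(f"wrote {len(reads)} reads "
          f"({reads_truth.total_reads} per truth bookkeeping)")
    print(f"planted {len(genome.precursors)} precursors "
          f"among {len(genome.decoys)} decoys on {len(genome.contigs)} contigs")
    print(f"planted {len(transcriptome.sites)} target sites "
          f"on {len(transcriptome.transcripts)} transcripts")
    print(f"outputs under {out}/")


if __name__ == "__main__":
    main()
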