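#!/usr/bin/env python
"""Classify clean tags against the mature miRNA reference.

Equal-length matching with at most one substitution assigns each tag to
its closest known plant miRNA; hits receive cci- names and are summarised
per family.  The remainder (tags explained by no homolog) is written out
as the input to novel discovery.
"""

from pathlib import Path

from mirseedling.conserved import classify_tags, summarize_families, write_conserved_table
from mirseedling.seqio import read_mature_fasta, read_tag_table, write_tag_table


def main() -> None:
    out = Path("results")
    tags = read_tag_table(out / "clean_tags.tsv")
    db = read_mature_fasta(out / "data" / "mature_reference.fa")
    hits, remainder = classify_tags(tags, db, max_mismatches=1)

    write_conserved_table(out / "conserved_mirnas.tsv", hits)
    write_tag_table(out / "unexplained_tags.tsv", remainder)
    with (out / "family_summary.tsv").open("w") as fh:
        fh.write("family\tmember_count\ttotal_read_count\n")
        for row in summarize_families(hits):
            fh.write(f"{row.family}\t{row.member_count}\t{row.total_read_count}\n")

    print(f"{len(tags)} clean tags against {len(db)} references")
    print(f"conserved: {len(hits)} tags "
          f"({sum(h.read_count for h in hits)} reads)")
    for row in summarize_families(hits)[:5]:
        print(f"  {row.family}: {row.member_count} member(s), "
              f"{row.total_read_count} reads")
    print(f"unexplained tags passed to novel discovery: {len(remainder)}")


if __name__ == "__main__":
    main()
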