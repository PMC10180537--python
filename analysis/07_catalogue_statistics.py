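#!/usr/bin/env python
"""Recompute the published-catalogue statistics.

Loads the shipped cumin miRNA catalogues (the published summary tables)
and recomputes their headline numbers from the raw column values: the
MFEI distribution of the 39 novel precursors, the MFEI >= 0.70 filter,
the read-count extremes, the copy-number gate, and the conserved
catalogue's maximum read count.
"""

import json
from pathlib import Path

from mirseedling.tables import (
    conserved_max_read_count,
    count_passing_mfei,
    family_partial_total,
    load_novel_catalogue,
    novel_mfei_statistics,
    novel_read_count_extremes,
)


def main() -> None:
    out = Path("results")
    out.mkdir(exist_ok=True)
    stats = novel_mfei_statistics()
    extremes = novel_read_count_extremes()
    df = load_novel_catalogue()
    summary = {
        "novel_entries": stats["n"],
        "mfei_mean": round(stats["mean"], 2),
        "mfei_sd": round(stats["sd"], 2),
        "mfei_min": stats["min"],
        "mfei_max": stats["max"],
        "passing_mfei_0.70": count_passing_mfei(),
        "read_count_top3": [extremes["highest"], extremes["second"],
                            extremes["third"]],
        "read_count_min": extremes["lowest"],
        "copy_number_gate_kept": int((df["read_count"] >= 5).sum()),
        "conserved_max_read_count": conserved_max_read_count(),
        "mir166_printed_family_reads": family_partial_total("MIR166"),
    }
    (out / "catalogue_statistics.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print(f"novel catalogue: {summary['novel_entries']} entries")
    print(f"MFEI mean +/- SD: {summary['mfei_mean']} +/- {summary['mfei_sd']} "
          f"(range {summary['mfei_min']}-{summary['mfei_max']})")
    print(f"entries passing MFEI >= 0.70: {summary['passing_mfei_0.70']}")
    print(f"read counts: top {summary['read_count_top3']}, "
          f"min {summary['read_count_min']}")
    print(f"queries passing the copy-number >= 5 gate: "
          f"{summary['copy_number_gate_kept']}")
    print(f"conserved catalogue maximum read count: "
          f"{summary['conserved_max_read_count']}")
    print(f"MIR166 printed-member read total: "
          f"{summary['mir166_printed_family_reads']}")


if __name__ == "__main__":
    main()
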