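"""End-to-end pipeline driver.

Runs the stages in the fixed order preprocess -> conserved -> novel ->
targets -> network, writing each stage's TSV artifacts plus a
machine-readable run manifest (JSON) into the output directory.  All
thresholds live in a single validated configuration object so a run is
fully self-describing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .conserved import classify_tags, summarize_families, write_conserved_table
from .network import build_network, degree_summary, export_sif
from .novel import NovelCriteria, call_novel, write_novel_table
from .preprocess import PreprocessConfig, run_preprocess
from .qpcr import read_ct_table, relative_expression_table
from .seqio import (
    read_fasta,
    read_fastq,
    read_mature_fasta,
    to_rna,
    write_fasta,
    write_tag_table,
    ReferenceSequence,
)
from .targets import TargetScoringScheme, filter_queries, scan_all, write_site_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "load_config"]


@dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    fastq: str = ""
    mature_reference: str = ""
    ncrna_reference: str = ""
    contigs: str = ""
    transcripts: str = ""
    ct_table: str = ""
    out_dir: str = "mirseedling_out"
    seed: int = 0
    log_level: str = "INFO"
    max_mismatches: int = 1
    min_copies: int = 5
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    criteria: NovelCriteria = field(default_factory=NovelCriteria)
    scoring: TargetScoringScheme = field(default_factory=TargetScoringScheme)

    def validate_inputs(self) -> None:
        problems = []
        for label, path in (
            ("fastq", self.fastq),
            ("mature_reference", self.mature_reference),
            ("ncrna_reference", self.ncrna_reference),
            ("contigs", self.contigs),
            ("transcripts", self.transcripts),
        ):
            if path and not Path(path).exists():
                problems.append(f"{label}: {path} does not exist")
        if not self.fastq:
            problems.append("fastq input is required")
        if problems:
            raise FileNotFoundError("; ".join(problems))


_NESTED = {
    "preprocess": PreprocessConfig,
    "criteria": NovelCriteria,
    "scoring": TargetScoringScheme,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - top_fields
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _NESTED:
            cls = _NESTED[key]
            sub_fields = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - sub_fields
            if bad:
                raise ValueError(f"unknown {key} key(s): {sorted(bad)}")
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute every configured stage; returns the run summary dict.

    Stages whose inputs are not configured (e.g. no Ct table) are
    skipped and noted in the manifest.
    """
    logging.basicConfig(level=config.log_level)
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"version": __version__, "seed": config.seed,
                               "stages": {}}

    # --- preprocess ---
    ncrna = read_fasta(config.ncrna_reference) if config.ncrna_reference else []
    logger.info("preprocess: adapter=%r minQ=%s len=[%s,%s]",
                config.preprocess.adapter_3p, config.preprocess.min_mean_quality,
                config.preprocess.min_len, config.preprocess.max_len)
    tags, accounting, lengths = run_preprocess(
        read_fastq(config.fastq), config.preprocess, ncrna
    )
    write_tag_table(out / "clean_tags.tsv", tags)
    with (out / "read_accounting.tsv").open("w") as handle:
        handle.write("category\tcount\n")
        for name, value in accounting.as_rows():
            handle.write(f"{name}\t{value}\n")
    with (out / "length_distribution.tsv").open("w") as handle:
        handle.write("length\tunique_tags\tpercent\n")
        for length, count, pct in lengths.as_rows():
            handle.write(f"{length}\t{count}\t{pct}\n")
    summary["stages"]["preprocess"] = {
        "total_reads": accounting.total_reads,
        "clean_unique_tags": accounting.clean_unique_tags,
        "modal_length": lengths.mode,
    }

    # --- conserved ---
    hits: list = []
    remainder = tags
    if config.mature_reference:
        db = read_mature_fasta(config.mature_reference)
        logger.info("conserved: %d references, max_mismatches=%d",
                    len(db), config.max_mismatches)
        hits, remainder = classify_tags(tags, db, config.max_mismatches)
        write_conserved_table(out / "conserved_mirnas.tsv", hits)
        with (out / "family_summary.tsv").open("w") as handle:
            handle.write("family\tmember_count\ttotal_read_count\n")
            for row in summarize_families(hits):
                handle.write(
                    f"{row.family}\t{row.member_count}\t{row.total_read_count}\n"
                )
    summary["stages"]["conserved"] = {
        "conserved_tags": len(hits),
        "unexplained_tags": len(remainder),
    }

    # --- novel ---
    calls: list = []
    if config.contigs:
        contigs = read_fasta(config.contigs)
        logger.info("novel: %d contigs, MFEI>=%.2f",
                    len(contigs), config.criteria.min_mfei)
        calls, rejected = call_novel(remainder, contigs,
                                     criteria=config.criteria)
        write_novel_table(out / "novel_mirnas.tsv", calls)
        write_fasta(
            out / "novel_precursors.fa",
            [
                ReferenceSequence(
                    seq_id=c.name, sequence=c.candidate.precursor_seq
                )
                for c in calls
            ],
        )
        with (out / "novel_structures.txt").open("w") as handle:
            for c in calls:
                handle.write(f">{c.name}\n{c.candidate.precursor_seq}\n"
                             f"{c.candidate.structure.dot_bracket} "
                             f"({c.candidate.structure.mfe:.2f})\n")
        with (out / "rejection_log.tsv").open("w") as handle:
            handle.write("tag\tcontig\tstart\tend\tstrand\tmfei\treason\n")
            for r in rejected:
                handle.write(
                    f"{to_rna(r.mature_tag.sequence)}\t{r.locus.contig_id}\t"
                    f"{r.locus.start}\t{r.locus.end}\t{r.locus.strand}\t"
                    f"{r.mfei:.2f}\t{r.verdict}\n"
                )
    summary["stages"]["novel"] = {"novel_mirnas": len(calls)}

    # --- targets + network ---
    n_sites = 0
    if config.transcripts:
        transcripts = read_fasta(config.transcripts)
        queries: list[tuple[str, str]] = []
        for h in filter_queries(hits, config.min_copies):
            queries.append((h.assigned_name, h.tag.sequence))
        for c in filter_queries(calls, config.min_copies):
            queries.append((c.name, c.sequence))
        logger.info("targets: %d queries (copy number >= %d), cutoff %.1f",
                    len(queries), config.min_copies,
                    config.scoring.expectation_cutoff)
        sites = scan_all(queries, transcripts, config.scoring)
        n_sites = len(sites)
        write_site_table(out / "target_sites.tsv", sites)
        g = build_network(sites)
        export_sif(g, out / "network")
        mirna_deg, target_deg = degree_summary(g)
        with (out / "degree_summary.tsv").open("w") as handle:
            handle.write("node\tkind\tdegree\n")
            for n, d in mirna_deg:
                handle.write(f"{n}\tmirna\t{d}\n")
            for n, d in target_deg:
                handle.write(f"{n}\ttarget\t{d}\n")
    summary["stages"]["targets"] = {"sites": n_sites}

    # --- qPCR ---
    if config.ct_table:
        ct = read_ct_table(config.ct_table)
        table = relative_expression_table(ct)
        table.to_csv(out / "qpcr_relative_expression.tsv", sep="\t", index=False)
        summary["stages"]["qpcr"] = {"assays": int(len(table))}

    manifest = {
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items()},
        },
        "summary": summary,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
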