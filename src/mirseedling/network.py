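"""miRNA-target network construction and annotation tabulation.

Builds the bipartite miRNA-target graph weighted by duplex MFE (more
negative = stronger interaction), computes degree summaries, tabulates
annotation-category percentages over annotated targets, and exports SIF
plus node/edge attribute tables that standard graph viewers can load.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .targets import TargetSite

__all__ = [
    "NetworkEdge",
    "build_network",
    "degree_summary",
    "category_percentages",
    "export_sif",
    "import_sif",
]


@dataclass(frozen=True)
class NetworkEdge:
    mirna_id: str
    target_id: str
    weight: float       # duplex MFE, kcal/mol
    expectation: float


def build_network(sites: Sequence[TargetSite]) -> nx.Graph:
    """Bipartite miRNA-target graph from predicted sites.

    Duplicate (mirna, transcript) pairs are reduced to the single best
    site (lowest expectation, then most negative duplex MFE).
    """
    best: dict[tuple[str, str], TargetSite] = {}
    for site in sites:
        key = (site.mirna_id, site.transcript_id)
        cur = best.get(key)
        if cur is None or (site.expectation, site.duplex_mfe) < (
            cur.expectation, cur.duplex_mfe
        ):
            best[key] = site
    g = nx.Graph()
    for (mirna, target), site in sorted(best.items()):
        g.add_node(mirna, kind="mirna")
        g.add_node(target, kind="target")
        g.add_edge(
            mirna, target, weight=site.duplex_mfe, expectation=site.expectation
        )
    return g


def degree_summary(g: nx.Graph) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """(miRNA target counts, target regulator counts), sorted descending,
    ties broken lexicographically."""
    mirnas = [(n, g.degree(n)) for n, d in g.nodes(data=True) if d["kind"] == "mirna"]
    targets = [(n, g.degree(n)) for n, d in g.nodes(data=True) if d["kind"] == "target"]
    key = lambda t: (-t[1], t[0])
    return sorted(mirnas, key=key), sorted(targets, key=key)


def category_percentages(
    target_ids: Sequence[str],
    annotation: Mapping[str, Sequence[str]],
) -> dict[str, tuple[int, float]]:
    """Per-category (count, percentage) over annotated targets.

    ``annotation`` maps target id -> category labels.  Percentages use the
    annotated-target denominator (each target counted once per category);
    targets with no annotation are reported under ``"unannotated"`` with a
    percentage over all targets.
    """
    annotated = [t for t in target_ids if annotation.get(t)]
    unannotated = [t for t in target_ids if not annotation.get(t)]
    counts: dict[str, int] = {}
    for t in annotated:
        for cat in set(annotation[t]):
            counts[cat] = counts.get(cat, 0) + 1
    out: dict[str, tuple[int, float]] = {}
    denom = len(annotated)
    for cat in sorted(counts, key=lambda c: (-counts[c], c)):
        out[cat] = (counts[cat], round(100.0 * counts[cat] / denom, 2))
    if unannotated:
        total = len(target_ids)
        out["unannotated"] = (
            len(unannotated),
            round(100.0 * len(unannotated) / total, 2),
        )
    return out


def export_sif(
    g: nx.Graph, prefix: str | Path, relation: str = "targets"
) -> tuple[Path, Path, Path]:
    """Write ``<prefix>.sif`` plus node/edge attribute TSVs.

    Returns the three paths.  Re-importing with :func:`import_sif`
    reproduces the identical network.
    """
    prefix = Path(prefix)
    sif = prefix.with_suffix(".sif")
    nodes = prefix.parent / (prefix.name + ".nodes.tsv")
    edges = prefix.parent / (prefix.name + ".edges.tsv")
    with sif.open("w") as handle:
        for u, v, d in sorted(g.edges(data=True)):
            mirna, target = (u, v) if g.nodes[u]["kind"] == "mirna" else (v, u)
            handle.write(f"{mirna}\t{relation}\t{target}\n")
    with nodes.open("w") as handle:
        handle.write("node\tkind\n")
        for n, d in sorted(g.nodes(data=True)):
            handle.write(f"{n}\t{d['kind']}\n")
    with edges.open("w") as handle:
        handle.write("mirna\ttarget\tduplex_mfe\texpectation\n")
        for u, v, d in sorted(g.edges(data=True)):
            mirna, target = (u, v) if g.nodes[u]["kind"] == "mirna" else (v, u)
            handle.write(
                f"{mirna}\t{target}\t{d['weight']:.2f}\t{d['expectation']:.2f}\n"
            )
    return sif, nodes, edges


def import_sif(prefix: str | Path) -> nx.Graph:
    """Rebuild a network exported by :func:`export_sif`."""
    prefix = Path(prefix)
    nodes = prefix.parent / (prefix.name + ".nodes.tsv")
    edges = prefix.parent / (prefix.name + ".edges.tsv")
    g = nx.Graph()
    with nodes.open() as handle:
        next(handle)
        for line in handle:
            node, kind = line.rstrip("\n").split("\t")
            g.add_node(node, kind=kind)
    with edges.open() as handle:
        next(handle)
        for line in handle:
            mirna, target, w, e = line.rstrip("\n").split("\t")
            g.add_edge(mirna, target, weight=float(w), expectation=float(e))
    return g
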