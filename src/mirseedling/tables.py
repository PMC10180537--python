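"""Published cumin miRNA catalogues and their summary statistics.

The package ships the published conserved- and novel-miRNA summary
catalogues for *Cuminum cyminum* as plain TSVs.  The functions here load
them and recompute the headline statistics — MFEI distribution of the
novel precursors, read-count extremes, the MFEI >= 0.70 filter — from the
raw table values at run time.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_novel_catalogue",
    "load_conserved_catalogue",
    "novel_mfei_statistics",
    "novel_read_count_extremes",
    "count_passing_mfei",
    "conserved_max_read_count",
    "family_partial_total",
]


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("mirseedling.data").joinpath(name).open() as handle:
        return pd.read_csv(handle, sep="\t", comment="#")


def load_novel_catalogue() -> pd.DataFrame:
    """The 39-entry novel miRNA catalogue (name, sequence, length,
    read_count, strand, mfei_of_precursor)."""
    return _read_packaged("cumin_novel_mirnas.tsv")


def load_conserved_catalogue() -> pd.DataFrame:
    """The per-family conserved miRNA summary catalogue."""
    return _read_packaged("cumin_conserved_mirnas.tsv")


def novel_mfei_statistics(df: pd.DataFrame | None = None) -> dict[str, float]:
    """Mean, sample SD, min and max of the precursor MFEI column."""
    if df is None:
        df = load_novel_catalogue()
    vals = df["mfei_of_precursor"].to_numpy(dtype=float)
    return {
        "n": int(len(vals)),
        "mean": float(np.mean(vals)),
        "sd": float(np.std(vals, ddof=1)),
        "min": float(np.min(vals)),
        "max": float(np.max(vals)),
    }


def count_passing_mfei(df: pd.DataFrame | None = None,
                       threshold: float = 0.70) -> int:
    """How many catalogue entries pass the MFEI >= threshold filter."""
    if df is None:
        df = load_novel_catalogue()
    return int((df["mfei_of_precursor"] >= threshold).sum())


def novel_read_count_extremes(df: pd.DataFrame | None = None) -> dict[str, int]:
    """Top-3 and minimum read counts of the novel catalogue."""
    if df is None:
        df = load_novel_catalogue()
    counts = df["read_count"].sort_values(ascending=False).to_numpy()
    return {
        "highest": int(counts[0]),
        "second": int(counts[1]),
        "third": int(counts[2]),
        "lowest": int(counts[-1]),
    }


def conserved_max_read_count(df: pd.DataFrame | None = None) -> int:
    if df is None:
        df = load_conserved_catalogue()
    return int(df["read_count"].max())


def family_partial_total(family: str, df: pd.DataFrame | None = None) -> int:
    """Summed read count of the catalogue's printed members of a family
    (a lower bound on the full family total, which includes unprinted
    members)."""
    if df is None:
        df = load_conserved_catalogue()
    return int(df.loc[df["family"] == family, "read_count"].sum())
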