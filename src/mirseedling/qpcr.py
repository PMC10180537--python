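"""qPCR relative expression.

Reduces replicate Ct tables to relative expression normalized to an
endogenous control (U6 in the miRNA assays this package targets), using
the 2^(-dCt) form with amplification efficiency fixed at 2 (overridable).
Biological x technical replicate designs are collapsed technical-first:
technical replicates of a sample are averaged, then statistics are taken
over biological samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from statistics import mean, stdev
import pandas as pd

__all__ = [
    "QpcrMeasurement",
    "QpcrResult",
    "relative_expression",
    "fold_change",
    "read_ct_table",
    "relative_expression_table",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate Ct values for one assay (a miRNA or the reference)."""

    assay_id: str
    ct: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ct:
            raise ValueError("at least one Ct replicate required")
        for c in self.ct:
            if not 0 < c < 45:
                raise ValueError(f"Ct {c} outside (0, 45)")


@dataclass(frozen=True)
class QpcrResult:
    assay_id: str
    mean_dct: float
    relative_expression: float   # efficiency^(-mean dCt)
    sd: float                    # sd of per-replicate relative expression


def relative_expression(
    target: QpcrMeasurement,
    reference: QpcrMeasurement,
    efficiency: float = 2.0,
) -> QpcrResult:
    """Relative expression of ``target`` normalized to ``reference``.

    Replicates are paired by index: per replicate
    ``dCt = Ct_target - Ct_reference``; the point estimate is
    ``efficiency^(-mean dCt)`` and the spread is the standard deviation of
    the per-replicate ``efficiency^(-dCt)`` values.
    """
    if len(target.ct) != len(reference.ct):
        raise ValueError(
            f"replicate count mismatch: {len(target.ct)} vs {len(reference.ct)}"
        )
    dct = [t - r for t, r in zip(target.ct, reference.ct)]
    per_rep = [efficiency ** (-d) for d in dct]
    sd = stdev(per_rep) if len(per_rep) > 1 else 0.0
    m = mean(dct)
    return QpcrResult(
        assay_id=target.assay_id,
        mean_dct=m,
        relative_expression=efficiency ** (-m),
        sd=sd,
    )


def fold_change(
    condition_a: QpcrResult, condition_b: QpcrResult, efficiency: float = 2.0
) -> float:
    """ddCt-form ratio between two conditions of the same assay."""
    if condition_a.assay_id != condition_b.assay_id:
        raise ValueError("fold change requires the same assay in both conditions")
    ddct = condition_a.mean_dct - condition_b.mean_dct
    return efficiency ** (-ddct)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format Ct TSV: assay_id, sample_id, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"assay_id", "sample_id", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s) {sorted(missing)}")
    return df


def relative_expression_table(
    ct: pd.DataFrame,
    reference_assay: str = "U6",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Relative expression per assay from a long-format Ct table.

    Technical replicates (rows sharing assay and sample) are averaged
    first; each biological sample then yields one dCt against the
    reference assay measured on the same sample, and assay-level
    statistics are computed over samples.
    """
    if reference_assay not in set(ct["assay_id"]):
        raise ValueError(f"reference assay {reference_assay!r} not in table")
    tech = (
        ct.groupby(["assay_id", "sample_id"], as_index=False)["ct"].mean()
    )
    ref = tech[tech["assay_id"] == reference_assay].set_index("sample_id")["ct"]
    rows = []
    for assay, grp in tech[tech["assay_id"] != reference_assay].groupby("assay_id"):
        grp = grp.set_index("sample_id")
        common = grp.index.intersection(ref.index)
        if common.empty:
            raise ValueError(f"assay {assay!r} shares no samples with reference")
        dct = (grp.loc[common, "ct"] - ref.loc[common]).to_numpy()
        per_sample = efficiency ** (-dct)
        rows.append(
            {
                "assay_id": assay,
                "n_samples": len(common),
                "mean_dct": float(dct.mean()),
                "relative_expression": float(efficiency ** (-dct.mean())),
                "sd": float(per_sample.std(ddof=1)) if len(common) > 1 else 0.0,
            }
        )
    out = pd.DataFrame(rows).sort_values("assay_id").reset_index(drop=True)
    return out
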