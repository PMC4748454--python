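"""Relative-expression normalization and detection filtering.

Normalized expression of a miRNA in a sample is the percentage of that
sample's miRNA-mapped reads assigned to it (reads mapping to the miRNA divided
by reads mapping to all miRNAs, x100). Columns of an unfiltered expression
matrix therefore sum to exactly 100.

The detection filter removes miRNAs supported by fewer than ``min_reads``
sequencing reads in total across the cohort, or detected (count > 0) in fewer
than ``min_subjects`` individuals. The cohort-wide reading of the read
threshold is deliberate: a per-sample reading would exclude the
single-individual, low-count species the detection analysis is about. After
filtering, expression is by default NOT renormalized, so abundant-miRNA
percentages keep their meaning as shares of all originally mapped reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .mirna_mapper import CountMatrix

DEFAULT_MIN_READS = 10
DEFAULT_MIN_SUBJECTS = 3


@dataclass
class ExpressionMatrix:
    """miRNA x sample normalized expression (percent of mapped miRNA reads)."""

    expression: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # covariate-adjusted matrices (residuals + mean) may dip below zero
        if not self.provenance.get("adjusted", False) and (self.expression.values < 0).any():
            raise ValueError("negative expression values")

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    def mean_expression(self) -> pd.Series:
        """Cohort mean normalized expression per miRNA."""
        return self.expression.mean(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        self.expression.to_csv(path, sep="\t", index_label="miRNA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def normalize(counts: CountMatrix) -> ExpressionMatrix:
    """Percent-of-mapped-reads normalization, per sample."""
    totals = counts.mapped_total
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"no mapped reads in sample(s): {list(zero.index)}")
    expr = 100.0 * counts.counts.div(totals, axis=1)
    return ExpressionMatrix(expr, {"normalization": "percent_of_mapped"})


@dataclass
class RemovedMirna:
    mirna: str
    total_reads: float
    n_subjects: int
    reasons: tuple[str, ...]


def detection_filter(
    counts: CountMatrix,
    min_reads: int = DEFAULT_MIN_READS,
    min_subjects: int = DEFAULT_MIN_SUBJECTS,
) -> tuple[CountMatrix, list[RemovedMirna]]:
    """Drop miRNAs below the evidence thresholds.

    Retained iff total reads across samples >= ``min_reads`` AND number of
    samples with count > 0 >= ``min_subjects``. The removed list records each
    exclusion with its reason(s). Unmapped totals are carried through
    unchanged.
    """
    if min_reads < 1 or min_subjects < 1:
        raise ValueError("thresholds must be >= 1")
    totals = counts.counts.sum(axis=1)
    presence = (counts.counts > 0).sum(axis=1)
    removed: list[RemovedMirna] = []
    keep: list[str] = []
    for mirna in counts.counts.index:
        reasons = []
        if totals[mirna] < min_reads:
            reasons.append(f"total_reads<{min_reads}")
        if presence[mirna] < min_subjects:
            reasons.append(f"subjects<{min_subjects}")
        if reasons:
            removed.append(
                RemovedMirna(mirna, float(totals[mirna]), int(presence[mirna]), tuple(reasons))
            )
        else:
            keep.append(mirna)
    filtered = CountMatrix(counts.counts.loc[keep], counts.unmapped.copy())
    return filtered, removed


def removed_to_tsv(removed: list[RemovedMirna], path: str | Path) -> None:
    rows = [
        {"miRNA": r.mirna, "total_reads": r.total_reads,
         "n_subjects": r.n_subjects, "reasons": ";".join(r.reasons)}
        for r in removed
    ]
    pd.DataFrame(rows, columns=["miRNA", "total_reads", "n_subjects", "reasons"]).to_csv(
        path, sep="\t", index=False
    )


def penetrance(counts: CountMatrix) -> tuple[pd.Series, list[str]]:
    """Per-miRNA number of samples with nonzero count, plus the ubiquitous set.

    The ubiquitous set contains the miRNAs detected in every sample.
    """
    pen = (counts.counts > 0).sum(axis=1).astype(int)
    n = len(counts.samples)
    ubiquitous = sorted(pen.index[pen == n])
    return pen, ubiquitous
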