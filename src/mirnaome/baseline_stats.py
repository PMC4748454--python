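"""Baseline descriptors of the circulating miRNAOme.

Covers the descriptive layer of the analysis: how concentrated the plasma
miRNA load is (top-k load fraction), which species are stably expressed
across individuals (mean / SEM ranking and the top-decile stable set), the
normal range of each miRNA (five-number summary across subjects), and the
haemolysis sentinel comparing expression variability of blood-cell-associated
miRNAs against the rest.

Stability is scored by relative SEM (SEM divided by mean) rather than raw
SEM: a stable set ranked by raw SEM would be dominated by lowly expressed
species, whereas the relative score lets stable miRNAs span several orders of
expression magnitude. Raw-SEM ranking remains available via ``score="sem"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .quantify import ExpressionMatrix

#: miRNAs reported as highly expressed by blood cells (erythrocyte and other
#: lineages); inflated by haemolysis, hence the sentinel set. Overridable.
BLOOD_CELL_MIRNAS = (
    "hsa-miR-486-5p",
    "hsa-miR-92a-3p",
    "hsa-miR-181a-5p",
    "hsa-miR-151a-3p",
    "hsa-let-7f-5p",
)


def load_fraction(expr: ExpressionMatrix, k: int) -> float:
    """Share of the total miRNA load carried by the k most abundant species.

    miRNAs are ranked by cohort mean normalized expression; the result is the
    top-k mean-expression sum divided by the all-miRNA sum, in [0, 1].
    """
    if expr.expression.empty:
        raise ValueError("empty expression matrix")
    if not 0 <= k <= len(expr.expression):
        raise ValueError(f"k={k} outside [0, {len(expr.expression)}]")
    means = expr.mean_expression().sort_values(ascending=False)
    total = means.sum()
    if total == 0:
        raise ValueError("all-zero expression matrix")
    return float(means.iloc[:k].sum() / total)


@dataclass
class StabilityReport:
    """Per-miRNA stability ranking across subjects."""

    table: pd.DataFrame  # columns: mean, sem, dispersion, rank, top_decile_stable
    score: str = "relative_sem"

    @property
    def top_decile(self) -> list[str]:
        return list(self.table.index[self.table["top_decile_stable"]])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="miRNA")


def stability_rank(expr: ExpressionMatrix, score: str = "relative_sem") -> StabilityReport:
    """Rank miRNAs by expression stability across subjects.

    SEM is the sample standard deviation (ddof=1) over sqrt(n). The default
    dispersion score is SEM/mean; miRNAs with zero mean have an undefined
    score and are ranked last, flagged. Ties break by higher mean, then name.
    The top decile (ceil(0.10 * n) miRNAs) is flagged as the stable set.
    """
    if score not in ("relative_sem", "sem"):
        raise ValueError(f"unknown stability score {score!r}")
    df = expr.expression
    n = df.shape[1]
    if n < 2:
        raise ValueError("stability ranking needs >= 2 subjects")
    mean = df.mean(axis=1)
    sem = df.std(axis=1, ddof=1) / math.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = sem / mean if score == "relative_sem" else sem.copy()
    undefined = ~np.isfinite(dispersion)
    order = pd.DataFrame(
        {"disp": dispersion.where(~undefined, np.inf), "neg_mean": -mean}
    )
    ranked = order.sort_values(["disp", "neg_mean"]).index.tolist()
    # stable sort above; break remaining ties by name
    ranked = sorted(ranked, key=lambda m: (order.loc[m, "disp"], order.loc[m, "neg_mean"], m))
    rank = pd.Series({m: i + 1 for i, m in enumerate(ranked)})
    k = math.ceil(0.10 * len(df))
    top = set(ranked[:k])
    table = pd.DataFrame(
        {
            "mean": mean,
            "sem": sem,
            "dispersion": dispersion,
            "dispersion_undefined": undefined,
            "rank": rank,
            "top_decile_stable": [m in top for m in df.index],
        },
        index=df.index,
    )
    return StabilityReport(table, score)


def _per_mirna_cv(df: pd.DataFrame) -> pd.Series:
    """Per-miRNA coefficient of variation across subjects, in percent."""
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    return cv


def cv_compare(
    expr: ExpressionMatrix,
    set_a: Sequence[str],
    set_b: Sequence[str],
    pooling: str = "per_mirna_mean",
) -> tuple[float, float]:
    """Mean expression variability (CV %) of two disjoint miRNA sets.

    Default pooling computes each miRNA's CV across subjects and averages
    within the set (a set-level summary of per-species variability);
    ``pooling="pooled"`` instead computes one CV over all values of the set.
    Used as the haemolysis check: blood-cell-associated miRNAs should not be
    more variable than the rest.
    """
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("both miRNA sets must be nonempty")
    if a & b:
        raise ValueError(f"miRNA sets overlap: {sorted(a & b)}")
    missing = (a | b) - set(expr.expression.index)
    if missing:
        raise ValueError(f"miRNAs not in matrix: {sorted(missing)}")
    if pooling not in ("per_mirna_mean", "pooled"):
        raise ValueError(f"unknown pooling {pooling!r}")

    def one(names: set[str]) -> float:
        sub = expr.expression.loc[sorted(names)]
        if pooling == "per_mirna_mean":
            return float(_per_mirna_cv(sub).mean())
        values = sub.values.ravel()
        return float(100.0 * values.std(ddof=1) / values.mean())

    return one(a), one(b)


@dataclass
class RangeTable:
    """Five-number summary (min, Q1, median, Q3, max) per miRNA."""

    table: pd.DataFrame
    quartile_convention: str = "linear interpolation between order statistics"

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write(f"# quartiles: {self.quartile_convention}\n")
            self.table.to_csv(handle, sep="\t", index_label="miRNA")


def range_table(expr: ExpressionMatrix) -> RangeTable:
    """Normal range of each miRNA's expression across subjects."""
    df = expr.expression
    if df.empty:
        raise ValueError("empty expression matrix")
    q = np.percentile(df.values, [0, 25, 50, 75, 100], axis=1, method="linear")
    table = pd.DataFrame(
        {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]},
        index=df.index,
    )
    return RangeTable(table)
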