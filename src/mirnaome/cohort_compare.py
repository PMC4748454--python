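"""Covariate comparisons: differential expression and BMI correlation.

Group comparisons (sex, smoking, obesity) use a per-miRNA two-sided
two-sample t-test — Welch's unequal-variance form by default, Student's
pooled form via ``equal_var=True``. Before a comparison, the contribution of
the other recorded factors can be eliminated by least-squares
residualization: each miRNA's expression is regressed on the nuisance
covariates (binary-encoded) and replaced by residuals plus the grand mean.

Fold changes are computed on a pseudocount-stabilized scale (half the
smallest nonzero value of the matrix is added to both group means), which
keeps the ordering finite when one group mean is zero. No multiple-testing
correction is applied by default; Benjamini-Hochberg adjustment is available
via ``adjust="bh"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ExpressionMatrix

BINARY_FACTORS = ("sex", "smoking", "obese")


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Read the subject metadata TSV (subject_id, sex, age, smoking, bmi, obese)."""
    meta = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    meta = meta.set_index("subject_id")
    if meta.index.duplicated().any():
        raise ValueError("duplicate subject ids in metadata")
    if (meta["bmi"] <= 0).any():
        raise ValueError("BMI must be positive")
    return meta


def encode_factor(meta: pd.DataFrame, factor: str) -> pd.Series:
    """Binary-encode a metadata factor (F/yes/True -> 1, M/no/False -> 0)."""
    col = meta[factor]
    if factor == "sex":
        return (col.astype(str).str.upper() == "F").astype(float)
    if factor == "smoking":
        return (col.astype(str).str.lower().isin(("yes", "true", "1"))).astype(float)
    if factor == "obese":
        return col.astype(bool).astype(float)
    return col.astype(float)


def residualize(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    factor_to_keep: str,
    nuisance_factors: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Remove nuisance-covariate contributions from every miRNA.

    Fits, per miRNA, an additive least-squares model of expression on all
    binary factors except ``factor_to_keep`` and returns residuals plus the
    miRNA's grand mean (so the expression scale is preserved). With no
    nuisance factors the matrix is returned unchanged. A rank-deficient
    design (confounded factors) is an error naming the collinear columns.
    """
    missing = set(expr.samples) - set(meta.index)
    if missing:
        raise ValueError(f"metadata missing subjects: {sorted(missing)}")
    if nuisance_factors is None:
        nuisance_factors = [f for f in BINARY_FACTORS if f != factor_to_keep]
    nuisance_factors = [f for f in nuisance_factors if f != factor_to_keep]
    if not nuisance_factors:
        return ExpressionMatrix(expr.expression.copy(), dict(expr.provenance))
    meta = meta.loc[expr.samples]
    design = np.column_stack(
        [np.ones(len(meta))] + [encode_factor(meta, f).values for f in nuisance_factors]
    )
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"confounded design: factors {list(nuisance_factors)} are collinear "
            f"(rank {rank} < {design.shape[1]})"
        )
    y = expr.expression.values.T  # subjects x miRNAs
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    grand_mean = expr.expression.mean(axis=1).values
    out = pd.DataFrame(
        (resid + grand_mean).T, index=expr.expression.index, columns=expr.samples
    )
    prov = dict(expr.provenance)
    prov["adjusted"] = True
    prov["residualized_against"] = list(nuisance_factors)
    prov["note"] = "factor elimination by additive least-squares residualization"
    return ExpressionMatrix(out, prov)


@dataclass
class DifferentialResult:
    """Per-factor differential-expression table.

    ``table`` columns: mean_<group1>, mean_<group0>, fold_change (>0, on the
    pseudocount scale, high over low), direction (up in which group),
    log2_fold_change, t, p, p_adjusted (optional), significant, flagged
    (zero variance in both groups -> test undefined).
    """

    factor: str
    group1: str
    group0: str
    table: pd.DataFrame
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        """Significant entries, ordered by descending fold change."""
        sig = self.table[self.table["significant"]]
        return sig.sort_values("fold_change", ascending=False)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="miRNA")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for i in range(n - 1, -1, -1):
        idx = order[i]
        running = min(running, p[idx] * n / (i + 1))
        adj[idx] = running
    return adj


def t_test_de(
    expr: ExpressionMatrix,
    groups: pd.Series | Sequence[int],
    alpha: float = 0.05,
    equal_var: bool = False,
    adjust: str = "none",
    factor: str = "group",
    group_names: tuple[str, str] = ("1", "0"),
) -> DifferentialResult:
    """Two-sided two-sample t-test per miRNA between two subject groups.

    ``groups`` holds binary labels aligned with the matrix columns (1 =
    group1). Both groups need >= 2 subjects. miRNAs with zero variance in
    both groups have an undefined test; they are flagged and excluded from
    the significant set. Fold change is mean_high/mean_low after adding a
    pseudocount of half the smallest nonzero matrix value.
    """
    labels = np.asarray(pd.Series(groups), dtype=float)
    if len(labels) != len(expr.samples):
        raise ValueError("group labels do not match matrix columns")
    mask1 = labels == 1
    mask0 = labels == 0
    if mask1.sum() < 2 or mask0.sum() < 2:
        raise ValueError("both groups need at least 2 subjects")
    values = expr.expression.values
    g1 = values[:, mask1]
    g0 = values[:, mask0]
    mean1 = g1.mean(axis=1)
    mean0 = g0.mean(axis=1)
    nonzero = values[values > 0]
    pseudo = 0.5 * nonzero.min() if len(nonzero) else 1.0
    high = np.maximum(mean1, mean0) + pseudo
    low = np.minimum(mean1, mean0) + pseudo
    fold = high / low
    log2fc = np.log2((mean1 + pseudo) / (mean0 + pseudo))
    flagged = (g1.std(axis=1, ddof=1) == 0) & (g0.std(axis=1, ddof=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(g1, g0, axis=1, equal_var=equal_var)
    p = np.where(flagged, np.nan, p)
    if adjust == "bh":
        ok = ~np.isnan(p)
        p_adj = np.full_like(p, np.nan)
        p_adj[ok] = bh_adjust(p[ok])
        p_for_calls = p_adj
    elif adjust == "none":
        p_adj = np.full_like(p, np.nan)
        p_for_calls = p
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    significant = ~flagged & (p_for_calls < alpha)
    name1, name0 = group_names
    table = pd.DataFrame(
        {
            f"mean_{name1}": mean1,
            f"mean_{name0}": mean0,
            "fold_change": fold,
            "direction": np.where(mean1 >= mean0, f"up_in_{name1}", f"up_in_{name0}"),
            "log2_fold_change": log2fc,
            "t": t,
            "p": p,
            "p_adjusted": p_adj,
            "significant": significant,
            "flagged": flagged,
        },
        index=expr.expression.index,
    )
    return DifferentialResult(factor, name1, name0, table, alpha)


def compare_factor(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    factor: str,
    alpha: float = 0.05,
    eliminate_others: bool = True,
    equal_var: bool = False,
    adjust: str = "none",
) -> DifferentialResult:
    """Full factor comparison: optional residualization, then the t-test."""
    if eliminate_others:
        expr = residualize(expr, meta, factor)
    labels = encode_factor(meta.loc[expr.samples], factor)
    names = {"sex": ("F", "M"), "smoking": ("smoker", "nonsmoker"),
             "obese": ("obese", "nonobese")}.get(factor, ("1", "0"))
    return t_test_de(expr, labels, alpha, equal_var, adjust, factor, names)


def bmi_correlation(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    mirnas: Sequence[str] | None = None,
    stratify_sex: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of each miRNA's expression with BMI.

    Returns a table with r and p per miRNA (and per sex stratum when
    requested). Zero-variance inputs give an undefined r, flagged as NaN.
    """
    meta = meta.loc[expr.samples]
    if len(expr.samples) < 3:
        raise ValueError("BMI correlation needs >= 3 subjects")
    names = list(mirnas) if mirnas is not None else list(expr.expression.index)
    missing = set(names) - set(expr.expression.index)
    if missing:
        raise ValueError(f"miRNAs not in matrix: {sorted(missing)}")
    bmi = meta["bmi"].astype(float).values

    def corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            return float("nan"), float("nan")
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)

    rows = []
    strata: list[tuple[str, np.ndarray]] = [("all", np.ones(len(bmi), dtype=bool))]
    if stratify_sex:
        sex = encode_factor(meta, "sex").values
        strata += [("F", sex == 1), ("M", sex == 0)]
    for name in names:
        values = expr.expression.loc[name].values.astype(float)
        for label, mask in strata:
            r, p = corr(values[mask], bmi[mask])
            rows.append({"miRNA": name, "stratum": label, "n": int(mask.sum()),
                         "r": r, "p": p})
    return pd.DataFrame(rows).set_index(["miRNA", "stratum"])


def heatmap_matrix(expr: ExpressionMatrix, mirnas: Sequence[str]) -> pd.DataFrame:
    """Row-standardized (mean 0, SD 1) expression, clipped to [-2, 2].

    The export format used for group-effect heat maps.
    """
    sub = expr.expression.loc[list(mirnas)]
    centered = sub.sub(sub.mean(axis=1), axis=0)
    sd = sub.std(axis=1, ddof=1).replace(0, np.nan)
    return centered.div(sd, axis=0).clip(-2, 2).fillna(0.0)
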