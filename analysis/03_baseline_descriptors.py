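"""Baseline descriptors of the simulated circulating miRNAOme.

Computes the descriptive layer from the pipeline's expression matrix:
penetrance and the ubiquitous set, top-k load fractions, the stability
ranking with its top-decile stable set, per-miRNA normal ranges, and a
haemolysis-style CV comparison between the most abundant species and the
rest. Also prints the packaged reference-cohort table summaries for
comparison.
"""

from pathlib import Path

import pandas as pd

from mirnaome.baseline_stats import cv_compare, load_fraction, range_table, stability_rank
from mirnaome.mirna_mapper import CountMatrix
from mirnaome.pipeline_io import fixture_summary
from mirnaome.quantify import ExpressionMatrix, penetrance

PIPE = Path("results/pipeline")
OUT = Path("results/analysis")


def main() -> None:
    if not PIPE.exists():
        raise SystemExit("run analysis/02_reads_to_counts.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    expr = ExpressionMatrix.from_tsv(PIPE / "expression.tsv")
    counts = CountMatrix.from_tsv(PIPE / "counts.tsv")

    pen, ubiquitous = penetrance(CountMatrix(counts.counts.loc[expr.expression.index]))
    pen.to_frame("n_subjects").to_csv(OUT / "penetrance.tsv", sep="\t")
    print(f"{len(expr.expression)} miRNAs detected; "
          f"{len(ubiquitous)} present in all {len(expr.samples)} subjects")

    l1, l10 = load_fraction(expr, 1), load_fraction(expr, 10)
    print(f"load fraction: top-1 {100 * l1:.1f} %, top-10 {100 * l10:.1f} % of mapped reads")

    report = stability_rank(expr)
    report.to_tsv(OUT / "stability.tsv")
    print(f"top-decile stable set: {len(report.top_decile)} miRNAs, e.g. "
          f"{report.top_decile[:3]}")

    ranges = range_table(expr)
    ranges.to_tsv(OUT / "ranges.tsv")

    abundant = expr.mean_expression().nlargest(5).index.tolist()
    rest = [m for m in expr.expression.index if m not in abundant]
    cv_top, cv_rest = cv_compare(expr, abundant, rest)
    print(f"CV: 5 most abundant {cv_top:.1f} % vs remainder {cv_rest:.1f} %")

    fx = fixture_summary()
    print("reference-cohort tables: "
          f"mean RNA mass {fx['mean_rna_mass_ug']} ug over 18 donors; "
          f"{fx['ubiquitous_mirna_count']} ubiquitous miRNAs, max "
          f"{fx['max_normalised_expression']} % ({fx['max_expression_mirna']})")


if __name__ == "__main__":
    main()
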