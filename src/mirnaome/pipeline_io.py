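"""End-to-end orchestration, configuration and packaged reference tables.

``run_pipeline`` executes qc -> tally -> map -> quantify -> stats -> compare
over a directory of per-subject FASTQ files, writing tab-separated artifacts
plus a machine-readable run manifest stamped with the configuration hash.
Completed stages whose outputs already carry the same configuration hash are
reused on rerun, so the pipeline is resumable per stage.

The packaged reference tables come from the 18-donor disease-free plasma
cohort this pipeline emulates: the per-subject RNA yield from 5 mL of plasma,
the 53 miRNAs detected in every donor with their mean normalised expression,
and the blood-cell-associated miRNA sentinel set used by the haemolysis
check.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import baseline_stats, cohort_compare, quantify, read_qc, tally
from ._fastq import read_fastq
from .mirna_mapper import CountMatrix, MatureReference, count_matrix
from .synthetic_data import DEFAULT_ADAPTER, CohortConfig, iter_subject_reads

STAGE_VERSION = "1"


# --------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Every path, threshold and policy the pipeline needs, in one record."""

    reference: str = "reference.fasta"
    reads_dir: str = "reads"
    metadata: str = "metadata.tsv"
    out_dir: str = "results"
    adapter: str = DEFAULT_ADAPTER
    min_median_q: int = 30
    min_len: int = 15
    max_len: int = 35
    max_mismatch: int = 1
    mode: str = "containment"
    ambiguous: str = "discard"
    min_reads: int = 10
    min_subjects: int = 3
    alpha: float = 0.05
    topk: int = 10
    blood_set: list[str] = field(default_factory=list)
    eliminate_others: bool = True
    adjust: str = "none"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_median_q <= 60:
            raise ValueError("min_median_q outside [0, 60]")
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("need 1 <= min_len <= max_len")
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha outside (0, 1)")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True,
                              default_flow_style=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        s = str(source)
        if isinstance(source, Path) or ("\n" not in s and Path(s).exists()):
            text = Path(s).read_text()
        else:
            text = s
        return cls(**yaml.safe_load(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# pipeline

def _find_fastqs(reads_dir: Path) -> dict[str, Path]:
    paths: dict[str, Path] = {}
    for pattern in ("*.fastq", "*.fq", "*.fastq.gz", "*.fq.gz"):
        for p in sorted(reads_dir.glob(pattern)):
            paths[p.name.split(".")[0]] = p
    if not paths:
        raise FileNotFoundError(f"no FASTQ files under {reads_dir}")
    return paths


def run_pipeline(config: PipelineConfig, resume: bool = True) -> Path:
    """Run every stage; returns the output directory.

    Any stage failure propagates with the stage name prepended. Stage outputs
    found with a matching config hash are reused when ``resume`` is true.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    manifest_path = out / "manifest.json"
    manifest: dict = {"config_hash": digest, "stage_version": STAGE_VERSION, "stages": {}}
    if resume and manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_hash") == digest and \
                previous.get("stage_version") == STAGE_VERSION:
            manifest = previous

    def done(stage: str, outputs: list[Path]) -> bool:
        return stage in manifest["stages"] and all(p.exists() for p in outputs)

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))

    config.to_yaml(out / "config.yaml")
    try:
        stage = "qc_tally"
        fastqs = _find_fastqs(Path(config.reads_dir))
        tally_paths = {sid: out / f"{sid}.tally.tsv" for sid in fastqs}
        if not done(stage, list(tally_paths.values())):
            qc_counts = {}
            for sid, fq in fastqs.items():
                clean, report = read_qc.qc_filter(
                    read_fastq(fq), config.adapter, config.min_median_q,
                    config.min_len, config.max_len,
                )
                report.to_tsv(out / f"{sid}.qc.tsv")
                table = tally.build_tally(clean, sid)
                table.to_tsv(tally_paths[sid])
                qc_counts[sid] = {"reads_in": report.reads_in, "reads_out": report.reads_out}
            record(stage, samples=qc_counts)

        stage = "map"
        counts_path, summary_path = out / "counts.tsv", out / "mapstats.tsv"
        if not done(stage, [counts_path, summary_path]):
            reference = MatureReference.from_fasta(config.reference)
            tallies = [tally.TallyTable.from_tsv(p, sid) for sid, p in tally_paths.items()]
            counts = count_matrix(tallies, reference, config.max_mismatch,
                                  config.mode, config.ambiguous)
            counts.to_tsv(counts_path)
            counts.summary_tsv(summary_path)
            record(stage, mapped_total=counts.mapped_total.to_dict())
        counts = CountMatrix.from_tsv(counts_path, summary_path)

        stage = "quantify"
        expr_path = out / "expression.tsv"
        if not done(stage, [expr_path, out / "removed.tsv", out / "penetrance.tsv"]):
            filtered, removed = quantify.detection_filter(
                counts, config.min_reads, config.min_subjects
            )
            if filtered.counts.empty:
                print(f"warning: detection filter removed every miRNA "
                      f"(min_subjects={config.min_subjects} vs "
                      f"{len(counts.samples)} samples?)")
            expr_full = quantify.normalize(counts)
            expr = quantify.ExpressionMatrix(
                expr_full.expression.loc[filtered.counts.index], expr_full.provenance
            )
            expr.to_tsv(expr_path)
            quantify.removed_to_tsv(removed, out / "removed.tsv")
            pen, ubiquitous = quantify.penetrance(filtered)
            pen.to_frame("n_subjects_detected").to_csv(
                out / "penetrance.tsv", sep="\t", index_label="miRNA")
            record(stage, retained=len(filtered.counts), removed=len(removed),
                   ubiquitous=len(ubiquitous))
        expr = quantify.ExpressionMatrix.from_tsv(expr_path)

        stage = "stats"
        stats_outputs = [out / "stability.tsv", out / "ranges.tsv", out / "load_fraction.tsv"]
        if not done(stage, stats_outputs):
            if not expr.expression.empty:
                baseline_stats.stability_rank(expr).to_tsv(out / "stability.tsv")
                baseline_stats.range_table(expr).to_tsv(out / "ranges.tsv")
                rows = [
                    {"k": k, "load_fraction": baseline_stats.load_fraction(expr, k)}
                    for k in range(1, min(config.topk, len(expr.expression)) + 1)
                ]
                pd.DataFrame(rows).to_csv(out / "load_fraction.tsv", sep="\t", index=False)
                info: dict = {"n_mirnas": len(expr.expression)}
                blood = [m for m in config.blood_set if m in expr.expression.index]
                rest = [m for m in expr.expression.index if m not in blood]
                if blood and rest:
                    cv_a, cv_b = baseline_stats.cv_compare(expr, blood, rest)
                    pd.DataFrame(
                        [{"set": "blood_cell", "cv_percent": cv_a},
                         {"set": "other", "cv_percent": cv_b}]
                    ).to_csv(out / "cv_compare.tsv", sep="\t", index=False)
                    info["cv_blood"], info["cv_other"] = cv_a, cv_b
                elif config.blood_set:
                    print("warning: blood-cell set not found in matrix; CV check skipped")
                record(stage, **info)
            else:
                for p in stats_outputs:
                    p.write_text("")
                record(stage, n_mirnas=0)

        stage = "compare"
        meta = cohort_compare.load_metadata(config.metadata)
        if not expr.expression.empty:
            n_calls = {}
            for factor in cohort_compare.BINARY_FACTORS:
                try:
                    result = cohort_compare.compare_factor(
                        expr, meta, factor, config.alpha,
                        config.eliminate_others, adjust=config.adjust,
                    )
                except ValueError as err:
                    if "collinear" not in str(err):
                        raise
                    print(f"warning: {factor}: {err}; comparing without "
                          "factor elimination")
                    result = cohort_compare.compare_factor(
                        expr, meta, factor, config.alpha, False,
                        adjust=config.adjust,
                    )
                result.to_tsv(out / f"de_{factor}.tsv")
                sig = result.significant
                if len(sig):
                    cohort_compare.heatmap_matrix(expr, sig.index).to_csv(
                        out / f"heatmap_{factor}.tsv", sep="\t", index_label="miRNA")
                n_calls[factor] = int(len(sig))
            cohort_compare.bmi_correlation(expr, meta, stratify_sex=True).to_csv(
                out / "bmi_correlation.tsv", sep="\t")
            record(stage, significant=n_calls)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def simulate_to_counts(
    config: CohortConfig,
    qc_kwargs: dict | None = None,
    map_kwargs: dict | None = None,
):
    """Stream a synthetic cohort through QC, tally and mapping, in memory.

    Returns (CountMatrix, SimulatedCohort-style truth tuple): the per-subject
    reads are never materialized on disk, which keeps full-scale recovery runs
    inside a laptop budget.
    """
    from .synthetic_data import CohortTruth, make_metadata, make_reference, sample_profile
    import numpy as np

    root = np.random.SeedSequence(config.rng_seed)
    meta_seed, ref_seed, prof_seed, *_ = root.spawn(3 + config.n_subjects)
    reference = make_reference(
        config.n_mirnas, config.mirna_length_range,
        np.random.default_rng(ref_seed).integers(2**31),
    )
    profile = sample_profile(
        reference, config.top1_target, config.top10_target,
        np.random.default_rng(prof_seed).integers(2**31),
    )
    metadata = make_metadata(config, np.random.default_rng(meta_seed))
    tallies = []
    abundances = {}
    qc_reports = {}
    for sid, reads, abund in iter_subject_reads(config, reference, profile, metadata):
        clean, report = read_qc.qc_filter(reads, config.adapter, **(qc_kwargs or {}))
        tallies.append(tally.build_tally(clean, sid))
        abundances[sid] = abund
        qc_reports[sid] = report
    counts = count_matrix(tallies, reference, **(map_kwargs or {}))
    truth = CohortTruth(
        profile.fractions, pd.DataFrame(abundances),
        config.noise_read_fraction, config.low_quality_fraction,
        list(config.planted_effects), config.haemolysis_spike,
    )
    return counts, truth, metadata, qc_reports


# --------------------------------------------------------------------------
# packaged reference tables

@dataclass
class StudyFixtures:
    """The emulated cohort's printed reference tables."""

    rna_mass: pd.DataFrame          # 18 subjects x total RNA mass (ug) from 5 mL plasma
    ubiquitous: pd.DataFrame        # the 53 everywhere-detected miRNAs + mean expression
    blood_cell_set: tuple[str, ...]

    def validate(self) -> None:
        if len(self.rna_mass) != 18:
            raise ValueError(f"RNA-mass table has {len(self.rna_mass)} rows, expected 18")
        if (self.ubiquitous["normalised_expression"] <= 0).any():
            raise ValueError("non-positive normalised expression in ubiquitous table")


def load_fixtures() -> StudyFixtures:
    data = resources.files("mirnaome") / "data"
    rna = pd.read_csv(str(data / "rna_mass_ug.tsv"), sep="\t")
    ubiq = pd.read_csv(str(data / "ubiquitous_mirnas.tsv"), sep="\t")
    blood = tuple(
        line.strip()
        for line in (data / "blood_cell_mirnas.txt").read_text().splitlines()
        if line.strip()
    )
    fixtures = StudyFixtures(rna, ubiq, blood)
    fixtures.validate()
    return fixtures


def fixture_summary(fixtures: StudyFixtures | None = None) -> dict:
    """Headline numbers of the packaged tables.

    Mean RNA mass is rounded half-up to 2 decimals (the convention the
    source tables use for their own summary).
    """
    if fixtures is None:
        fixtures = load_fixtures()
    fixtures.validate()
    mean = float(
        Decimal(str(fixtures.rna_mass["total_rna_ug"].mean())).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )
    expr = fixtures.ubiquitous.set_index("miRNA")["normalised_expression"]
    return {
        "mean_rna_mass_ug": mean,
        "ubiquitous_mirna_count": int(len(expr)),
        "max_normalised_expression": float(expr.max()),
        "max_expression_mirna": str(expr.idxmax()),
    }
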