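"""Synthetic plasma small-RNA cohort generator.

Produces everything the pipeline consumes — a mature-miRNA reference FASTA, a
gzipped FASTQ per subject, a metadata table and a ground-truth record — with
the statistical structure the analysis assumes about plasma:

* a heavily top-skewed abundance profile (one dominant species around 60 % of
  the miRNA load, the top ten around 90 %, a geometrically decaying tail
  spanning several orders of magnitude),
* between-subject biological variation (lognormal, configurable CV) plus
  optional planted covariate effects (fold changes tied to sex, smoking or
  obesity) and an optional haemolysis spike in chosen subjects,
* read anatomy of an adapter-ligated small-RNA library: the insert followed
  by the 3' adapter, truncated (or padded) to a fixed read length,
* sequencing noise: per-base substitution errors on the insert, a configurable
  fraction of off-target random-sequence reads, and a two-component quality
  model ("good" reads all >= Q35, "bad" reads with median < Q30) so the Q30
  screen's pass set is exactly knowable.

Everything is bit-for-bit reproducible from the configured seed.
"""

from __future__ import annotations

import json
import math
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from ._fastq import ReadRecord, write_fastq
from .mirna_mapper import MatureReference

#: Illumina small-RNA 3' adapter (TruSeq), the default ligated adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

GOOD_Q = 38   # every base of a "good" read
BAD_Q = 20    # every base of a "bad" read: median 20 < Q30 screen


# --------------------------------------------------------------------------
# configuration and truth containers

@dataclass
class PlantedEffect:
    """Multiplicative abundance effect tied to a binary covariate.

    ``fold`` multiplies the miRNA's abundance, before renormalization, in
    subjects positive for ``factor`` (sex=F, smoking=yes, obese=True).
    """

    mirna: str
    factor: str        # "sex" | "smoking" | "obese"
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold change must be > 0")
        if self.factor not in ("sex", "smoking", "obese"):
            raise ValueError(f"unknown factor {self.factor!r}")


@dataclass
class HaemolysisSpike:
    """Multiply a blood-cell miRNA set in one subject, before renormalization."""

    subject_id: str
    mirnas: tuple[str, ...]
    multiplier: float = 10.0


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    Defaults emulate the 18-donor study design the pipeline targets: 9
    females / 9 males, 4 smokers in each sex, 7 obese females and 2 obese
    males (obese = BMI >= ``obesity_bmi_threshold``).
    """

    n_subjects: int = 18
    reads_per_subject: int = 100_000
    n_mirnas: int = 200
    mirna_length_range: tuple[int, int] = (18, 25)
    top1_target: float = 0.60
    top10_target: float = 0.90
    seq_error_rate: float = 0.005
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    noise_read_fraction: float = 0.10
    low_quality_fraction: float = 0.05
    biological_cv: float = 0.15
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    haemolysis_spike: HaemolysisSpike | None = None
    smoking_fraction: float = 4 / 9
    obese_per_sex: tuple[float, float] = (7 / 9, 2 / 9)  # (F, M)
    obesity_bmi_threshold: float = 30.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in ("seq_error_rate", "noise_read_fraction", "low_quality_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if not set(self.adapter.upper()) <= set("ACGT"):
            raise ValueError(f"adapter contains non-ACGT characters: {self.adapter!r}")
        self.adapter = self.adapter.upper()


@dataclass
class CohortTruth:
    """Generator-side ground truth for recovery tests.

    ``abundances``: per-subject realized miRNA fractions (summing to 1 over
    the reference; the off-target noise fraction is recorded separately).
    """

    profile: pd.Series                      # cohort-level baseline fractions
    abundances: pd.DataFrame                # miRNA x subject realized fractions
    noise_read_fraction: float
    low_quality_fraction: float
    planted_effects: list[PlantedEffect]
    haemolysis_spike: HaemolysisSpike | None

    def mean_abundance(self) -> pd.Series:
        """Cohort mean of the realized per-subject fractions."""
        return self.abundances.mean(axis=1)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "profile": self.profile.round(12).to_dict(),
            "abundances": {s: self.abundances[s].round(12).to_dict()
                           for s in self.abundances.columns},
            "noise_read_fraction": self.noise_read_fraction,
            "low_quality_fraction": self.low_quality_fraction,
            "planted_effects": [asdict(e) for e in self.planted_effects],
            "haemolysis_spike": asdict(self.haemolysis_spike)
            if self.haemolysis_spike else None,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        payload = json.loads(Path(path).read_text())
        spike = payload["haemolysis_spike"]
        return cls(
            pd.Series(payload["profile"]),
            pd.DataFrame(payload["abundances"]),
            payload["noise_read_fraction"],
            payload["low_quality_fraction"],
            [PlantedEffect(**e) for e in payload["planted_effects"]],
            HaemolysisSpike(spike["subject_id"], tuple(spike["mirnas"]),
                            spike["multiplier"]) if spike else None,
        )


# --------------------------------------------------------------------------
# reference and abundance profile

def make_reference(
    n_mirnas: int,
    length_range: tuple[int, int] = (18, 25),
    rng_seed: int = 0,
    max_attempts: int | None = None,
) -> MatureReference:
    """Random mature-miRNA reference with unambiguous one-mismatch assignment.

    Entries are uniform random DNA of lengths drawn from ``length_range``;
    any two equal-length entries are kept at Hamming distance >= 3, so a read
    one substitution away from an entry cannot also be within one mismatch of
    another equal-length entry. Deterministic given the seed; raises if the
    requested density of sequences cannot be placed.
    """
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    lo, hi = length_range
    if not (15 <= lo <= hi <= 35):
        raise ValueError("length_range must lie within [15, 35]")
    rng = np.random.default_rng(rng_seed)
    by_length: dict[int, list[np.ndarray]] = {}
    entries: dict[str, str] = {}
    if max_attempts is None:
        max_attempts = 200 + 60 * n_mirnas
    attempts = 0
    width = len(str(n_mirnas))
    while len(entries) < n_mirnas:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {n_mirnas} sequences at pairwise Hamming "
                f"distance >= 3 within {max_attempts} attempts; "
                "enlarge length_range or reduce n_mirnas"
            )
        attempts += 1
        length = int(rng.integers(lo, hi + 1))
        arr = rng.choice(_BASES, size=length)
        if any(int((arr != other).sum()) < 3 for other in by_length.get(length, [])):
            continue
        by_length.setdefault(length, []).append(arr)
        name = f"syn-miR-{len(entries) + 1:0{width}d}"
        entries[name] = arr.tobytes().decode()
    return MatureReference(entries, version=f"synthetic-n{n_mirnas}-seed{rng_seed}")


@dataclass
class AbundanceProfile:
    """Cohort-level relative abundance per reference miRNA (sums to 1)."""

    fractions: pd.Series

    def __post_init__(self) -> None:
        if (self.fractions < 0).any():
            raise ValueError("negative abundance fraction")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {self.fractions.sum()}, not 1")

    def sorted_fractions(self) -> pd.Series:
        return self.fractions.sort_values(ascending=False)


def sample_profile(
    reference: MatureReference,
    top1_target: float = 0.60,
    top10_target: float = 0.90,
    rng_seed: int = 0,
    mid_decay: float = 0.8,
    tail_decay: float = 0.95,
) -> AbundanceProfile:
    """Top-skewed abundance profile hitting the requested concentration targets.

    The most abundant species gets exactly ``top1_target``; ranks 2-10 share
    ``top10_target - top1_target`` by a geometric law (ratio ``mid_decay``);
    the remaining mass decays geometrically over the tail ranks (ratio
    ``tail_decay``, steepened automatically if needed to keep the profile
    non-increasing), spreading tail expression over orders of magnitude.
    Which reference entry receives which rank is a seeded permutation.
    """
    if not 0 < top1_target <= top10_target <= 1:
        raise ValueError("need 0 < top1_target <= top10_target <= 1")
    n = len(reference)
    if n < 10:
        raise ValueError("reference must have >= 10 entries for a top-10 target")
    mid_mass = top10_target - top1_target
    mid_w = mid_decay ** np.arange(9)
    mid = mid_mass * mid_w / mid_w.sum()
    if mid[0] > top1_target + 1e-12:
        raise ValueError(
            f"rank-2 fraction {mid[0]:.4f} would exceed top1_target {top1_target}"
        )
    tail_mass = 1.0 - top10_target
    n_tail = n - 10
    if n_tail == 0:
        if tail_mass > 1e-12:
            raise ValueError("top10_target < 1 needs more than 10 reference entries")
        tail = np.array([])
    else:
        # rank-10 fraction is the ceiling for the tail start; with no mass in
        # ranks 2-10 (degenerate equal targets) the ceiling does not apply
        floor = mid[-1]
        tail = None
        for q in (tail_decay, 0.97, 0.99, 0.995, 0.999, 1.0):
            w = q ** np.arange(n_tail) if q < 1.0 else np.ones(n_tail)
            cand = tail_mass * w / w.sum()
            if mid_mass < 1e-9 or cand[0] <= floor + 1e-12:
                tail = cand
                break
        if tail is None:
            raise ValueError(
                f"tail mass {tail_mass:.3f} over {n_tail} entries cannot stay "
                f"below the rank-10 fraction {floor:.5f}"
            )
    ranked = np.concatenate([[top1_target], mid, tail])
    rng = np.random.default_rng(rng_seed)
    names = np.array(list(reference.entries))
    order = rng.permutation(n)
    fractions = pd.Series(0.0, index=names)
    fractions.iloc[order] = ranked
    return AbundanceProfile(fractions)


# --------------------------------------------------------------------------
# metadata

def make_metadata(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Subject metadata table with the configured covariate balance.

    Subjects are FA01..FAxx (female) then MA01..MAxx (male). Smoking and
    obesity are assigned to seeded random subsets within each sex; BMI is
    drawn consistently with the obesity label (obese = BMI >= threshold).
    """
    n = config.n_subjects
    n_f = (n + 1) // 2
    n_m = n - n_f
    rows = []
    for sex, count, prefix in (("F", n_f, "FA"), ("M", n_m, "MA")):
        n_smoke = round(config.smoking_fraction * count)
        frac_ob = config.obese_per_sex[0] if sex == "F" else config.obese_per_sex[1]
        n_obese = round(frac_ob * count)
        smokers = set(rng.choice(count, size=n_smoke, replace=False))
        obese = set(rng.choice(count, size=n_obese, replace=False))
        for i in range(count):
            is_ob = i in obese
            thr = config.obesity_bmi_threshold
            bmi = float(rng.uniform(thr, thr + 16) if is_ob else rng.uniform(18, thr - 0.5))
            rows.append(
                {
                    "subject_id": f"{prefix}{i + 1:02d}",
                    "sex": sex,
                    "age": int(rng.integers(19, 68)),
                    "smoking": "yes" if i in smokers else "no",
                    "bmi": round(bmi, 1),
                    "obese": bool(round(bmi, 1) >= thr),
                }
            )
    return pd.DataFrame(rows).set_index("subject_id")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="subject_id")


# --------------------------------------------------------------------------
# read simulation

def realized_abundance(
    profile: AbundanceProfile,
    config: CohortConfig,
    subject_meta: pd.Series,
    rng: np.random.Generator,
) -> pd.Series:
    """One subject's true miRNA fractions.

    The cohort profile is perturbed by mean-1 lognormal noise with the
    configured biological CV, multiplied by any planted effects matching the
    subject's covariates and by the haemolysis spike if this is the spiked
    subject, then renormalized to sum to 1.
    """
    x = profile.fractions.to_numpy(copy=True)
    cv = config.biological_cv
    if cv > 0:
        sigma = math.sqrt(math.log(1 + cv * cv))
        x = x * rng.lognormal(-sigma * sigma / 2, sigma, size=len(x))
    names = profile.fractions.index
    positive = {
        "sex": str(subject_meta["sex"]).upper() == "F",
        "smoking": str(subject_meta["smoking"]).lower() in ("yes", "true", "1"),
        "obese": bool(subject_meta["obese"]),
    }
    for effect in config.planted_effects:
        if positive[effect.factor]:
            idx = names.get_loc(effect.mirna)
            x[idx] *= effect.fold
    spike = config.haemolysis_spike
    if spike is not None and spike.subject_id == subject_meta.name:
        for m in spike.mirnas:
            x[names.get_loc(m)] *= spike.multiplier
    return pd.Series(x / x.sum(), index=names)


def _mutate(insert: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> bytes:
    out = insert.copy()
    for pos in positions:
        current = out[pos]
        choices = _BASES[_BASES != current]
        out[pos] = rng.choice(choices)
    return out.tobytes()


def simulate_subject(
    reference: MatureReference,
    profile: AbundanceProfile,
    config: CohortConfig,
    subject_meta: pd.Series,
    rng_seed: int | np.random.SeedSequence,
) -> tuple[list[ReadRecord], pd.Series]:
    """Simulate one subject's raw reads; returns (reads, true abundances).

    Reads are the subject's miRNA inserts (multinomial draw from the realized
    abundances, per-base substitution errors at ``seq_error_rate``) plus a
    ``noise_read_fraction`` share of random off-target inserts; every insert
    gets the 3' adapter appended and the read is truncated or padded to
    ``read_length``. A ``low_quality_fraction`` share of reads receives the
    "bad" quality string (median < Q30); the rest are uniformly good.
    """
    rng = np.random.default_rng(rng_seed)
    abund = realized_abundance(profile, config, subject_meta, rng)
    n_reads = config.reads_per_subject
    n_noise = int(rng.binomial(n_reads, config.noise_read_fraction))
    counts = rng.multinomial(n_reads - n_noise, abund.to_numpy())

    adapter = config.adapter
    rlen = config.read_length
    pad = "A" * rlen

    def finish(insert: str) -> str:
        return (insert + adapter + pad)[:rlen]

    seqs: list[str] = []
    err = config.seq_error_rate
    for name, count in zip(abund.index, counts):
        if count == 0:
            continue
        insert = reference.entries[name]
        L = len(insert)
        base_read = finish(insert)
        if err == 0:
            seqs.extend([base_read] * count)
            continue
        n_err = int(rng.binomial(count * L, err))
        flat = rng.choice(count * L, size=n_err, replace=False) if n_err else np.array([], int)
        by_read: dict[int, list[int]] = {}
        for f in sorted(flat.tolist()):
            by_read.setdefault(f // L, []).append(f % L)
        arr = np.frombuffer(insert.encode(), dtype=np.uint8)
        reads = [base_read] * count
        for ridx, positions in by_read.items():
            mutated = _mutate(arr, np.array(positions), rng).decode()
            reads[ridx] = finish(mutated)
        seqs.extend(reads)
    lo, hi = config.mirna_length_range
    for _ in range(n_noise):
        length = int(rng.integers(lo, hi + 1))
        seqs.append(finish(rng.choice(_BASES, size=length).tobytes().decode()))

    order = rng.permutation(len(seqs))
    bad = rng.random(len(seqs)) < config.low_quality_fraction
    good_q = chr(GOOD_Q + 33) * rlen
    bad_q = chr(BAD_Q + 33) * rlen
    sid = subject_meta.name
    records = [
        ReadRecord(f"{sid}_{i}", seqs[j], bad_q if bad[j] else good_q)
        for i, j in enumerate(order)
    ]
    return records, abund


def iter_subject_reads(
    config: CohortConfig,
    reference: MatureReference | None = None,
    profile: AbundanceProfile | None = None,
    metadata: pd.DataFrame | None = None,
) -> Iterator[tuple[str, list[ReadRecord], pd.Series]]:
    """Stream (subject_id, reads, true abundances) per subject.

    Builds reference/profile/metadata from the config when not supplied; all
    randomness derives from ``config.rng_seed``.
    """
    root = np.random.SeedSequence(config.rng_seed)
    meta_seed, ref_seed, prof_seed, *subject_seeds = root.spawn(3 + config.n_subjects)
    if reference is None:
        reference = make_reference(
            config.n_mirnas, config.mirna_length_range,
            np.random.default_rng(ref_seed).integers(2**31),
        )
    if profile is None:
        profile = sample_profile(
            reference, config.top1_target, config.top10_target,
            np.random.default_rng(prof_seed).integers(2**31),
        )
    if metadata is None:
        metadata = make_metadata(config, np.random.default_rng(meta_seed))
    if len(metadata) != config.n_subjects:
        raise ValueError("metadata rows do not match n_subjects")
    for seed, (sid, row) in zip(subject_seeds, metadata.iterrows()):
        reads, abund = simulate_subject(reference, profile, config, row, seed)
        yield sid, reads, abund


@dataclass
class SimulatedCohort:
    """Handles to everything a cohort simulation produced."""

    reference: MatureReference
    profile: AbundanceProfile
    metadata: pd.DataFrame
    truth: CohortTruth
    fastq_paths: dict[str, Path] = field(default_factory=dict)
    out_dir: Path | None = None


def simulate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
    metadata: pd.DataFrame | None = None,
) -> SimulatedCohort:
    """Generate the full cohort; write FASTA/FASTQ/metadata/truth when given a directory.

    With ``out_dir=None`` nothing touches disk and the per-subject reads are
    not retained (use :func:`iter_subject_reads` to stream them); the
    returned truth is identical either way.
    """
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
    if metadata is None:
        metadata = make_metadata(config, np.random.default_rng(meta_seed))

    out_path: Path | None = None
    if out_dir is not None:
        out_path = Path(out_dir)
        if out_path.exists() and any(out_path.iterdir()):
            if not overwrite:
                raise FileExistsError(
                    f"output directory {out_path} exists and is not empty "
                    "(pass overwrite=True to replace it)"
                )
            shutil.rmtree(out_path)
        out_path.mkdir(parents=True, exist_ok=True)

    abundances: dict[str, pd.Series] = {}
    fastq_paths: dict[str, Path] = {}
    for sid, reads, abund in iter_subject_reads(config, reference, profile, metadata):
        abundances[sid] = abund
        if out_path is not None:
            fq = out_path / f"{sid}.fastq.gz"
            write_fastq(fq, reads)
            fastq_paths[sid] = fq
    truth = CohortTruth(
        profile.fractions,
        pd.DataFrame(abundances),
        config.noise_read_fraction,
        config.low_quality_fraction,
        list(config.planted_effects),
        config.haemolysis_spike,
    )
    if out_path is not None:
        reference.to_fasta(out_path / "reference.fasta")
        write_metadata(metadata, out_path / "metadata.tsv")
        truth.to_json(out_path / "truth.json")
    return SimulatedCohort(reference, profile, metadata, truth, fastq_paths, out_path)
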