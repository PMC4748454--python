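"""Simulate the 18-donor plasma small-RNA cohort used by the downstream analyses.

Generates a 200-species mature-miRNA reference, a top-skewed abundance profile
(top-1 = 60 %, top-10 = 90 % of the miRNA load), and one gzipped FASTQ per
subject (9 F / 9 M, 4 smokers per sex, 7 obese F / 2 obese M), with planted
covariate effects for the comparison analyses to recover:

* three miRNAs up 4x in females,
* two miRNAs down 4x in smokers (a smoking-associated global down-regulation),
* two miRNAs up 3x in obese subjects.

Reads per subject are kept at 20,000 so the whole analysis chain reruns in
seconds; the statistical structure matches the full-scale generator defaults.
"""

import sys
from pathlib import Path

from mirnaome.synthetic_data import CohortConfig, PlantedEffect, simulate_cohort

OUT = Path("results/cohort")
SEED = 20160209


def planted_effects(width: int = 3) -> list[PlantedEffect]:
    # reference names are syn-miR-001 ... syn-miR-200; plant effects on
    # mid-abundance species so they survive the detection filter
    name = lambda i: f"syn-miR-{i:0{width}d}"
    return (
        [PlantedEffect(name(i), "sex", 4.0) for i in (11, 12, 13)]
        + [PlantedEffect(name(i), "smoking", 0.25) for i in (21, 22)]
        + [PlantedEffect(name(i), "obese", 3.0) for i in (31, 32)]
    )


def main() -> None:
    config = CohortConfig(
        n_subjects=18,
        reads_per_subject=20_000,
        n_mirnas=200,
        planted_effects=planted_effects(),
        rng_seed=SEED,
    )
    cohort = simulate_cohort(config, OUT, overwrite="--overwrite" in sys.argv)
    meta = cohort.metadata
    print(f"cohort written to {OUT}/ ({len(cohort.fastq_paths)} FASTQ files)")
    print(f"  sex counts:     {meta['sex'].value_counts().to_dict()}")
    print(f"  smokers:        {(meta['smoking'] == 'yes').sum()}")
    print(f"  obese (BMI>=30): {meta['obese'].sum()}")
    top = cohort.profile.sorted_fractions()
    print(f"  profile: top-1 {top.iloc[0]:.3f}, top-10 {top.iloc[:10].sum():.3f}")
    print(f"  planted effects: {len(config.planted_effects)}")


if __name__ == "__main__":
    main()
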