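# mirnaome

Baseline profiling of the circulating miRNAOme in human plasma from small-RNA
sequencing data.

Cell-free microRNAs are leading biomarker candidates, but candidate screens
need baseline data: which miRNAs are present in disease-free plasma, at what
levels, how variable they are between individuals, and how sex, smoking and
body-mass index shift them. This package implements the complete analysis
chain from raw adapter-ligated small-RNA reads to those baseline statistics,
together with a fully ground-truthed synthetic cohort generator so every
stage can be validated against known truth. It is aimed at researchers
designing or auditing plasma miRNA biomarker studies.

## The analysis

For each subject, reads are quality-screened (whole-read retention at median
Phred ≥ Q30), 3′ adapter-trimmed, and restricted to miRNA-sized inserts
(15–35 nt). Cleaned reads collapse into unique-sequence tallies, which are
assigned to a mature miRNA reference allowing at most one mismatch: sequence
*s* hits reference entry *m* when the shorter is contained in the longer at
some ungapped offset with Hamming distance ≤ 1 (ambiguous assignments are
discarded by default). Normalised expression of miRNA *m* in sample *j* is

    E_mj = 100 · c_mj / Σ_m c_mj          (percent of mapped miRNA reads)

miRNAs with fewer than 10 supporting reads cohort-wide, or detected in fewer
than 3 subjects, are excluded. On the filtered matrix the package computes:

- **penetrance** — number of subjects in which each miRNA is detected, and
  the ubiquitous (all-subjects) set;
- **load fraction** — share of the total miRNA load carried by the top-k
  species (in plasma a single species can carry ~60 % and the top ten ~90 %);
- **stability ranking** — per-miRNA mean and SEM across subjects, ranked by
  relative SEM (SEM/mean), with the top decile flagged as the stable set;
- **normal ranges** — five-number summaries per miRNA;
- **haemolysis sentinel** — coefficient of variation (%) of
  blood-cell-associated miRNAs versus the rest;
- **covariate comparisons** — per-miRNA two-sided Welch t-tests between
  sex/smoking/obesity groups after least-squares elimination of the other
  factors, fold changes on a pseudocount-stabilised scale, and Pearson
  correlation of expression with BMI.

The synthetic generator emulates the study design these analyses assume:
18 donors (9 F / 9 M, 4 smokers per sex, 7 obese females and 2 obese males),
a top-skewed abundance profile with a geometrically decaying tail spanning
orders of magnitude, lognormal between-subject variation, planted covariate
fold changes, optional haemolysis spikes, sequencing errors, off-target
reads, and a two-component quality model.

## Worked example

```
python analysis/01_simulate_cohort.py
python analysis/02_reads_to_counts.py
python analysis/03_baseline_descriptors.py
python analysis/04_covariate_effects.py
```

which prints (abridged):

```
cohort written to results/cohort/ (18 FASTQ files)
  profile: top-1 0.600, top-10 0.900
pipeline outputs in results/pipeline/
  FA01 QC: 19014/20000 reads kept
  detected after filter: 109 miRNAs (91 removed below thresholds)
109 miRNAs detected; 71 present in all 18 subjects
load fraction: top-1 59.5 %, top-10 89.6 % of mapped reads
CV: 5 most abundant 14.0 % vs remainder 50.2 %
sex: 2 significant miRNAs (P < 0.05); recovered 2/3 planted effects ...
BMI correlation of obesity-associated miRNAs: r in [0.61, 0.76]
```

At 20,000 reads/subject the pipeline recovers the generator's planted
structure: the top-1/top-10 load fractions land on the 60 %/90 % targets,
the detection filter trims the unsupported tail, and the planted covariate
effects that carry read support are called with the correct direction.
Planted species that fall in the extreme low-abundance tail can drop below
the 10-read detection floor — exactly the behaviour the filter is for.

Every stage is also available as a CLI (`mirnaome simulate|qc|tally|map|
quantify|stats|compare|run`) and as plain library functions.

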