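# Methods

## Scope and model

The package treats a plasma small-RNA sequencing experiment as a chain of
well-defined transformations:

reads → QC-screened reads → unique-sequence tallies → per-miRNA counts →
normalised expression (percent of mapped miRNA reads) → baseline statistics
and covariate comparisons.

The statistical model underlying both the generator and the analyses is:
each subject carries a vector of relative miRNA abundances obtained by
perturbing a cohort-level profile with mean-one lognormal noise,
multiplying in any covariate effects, and renormalising; sequencing then
draws reads multinomially from that vector, corrupts them with independent
per-base substitution errors, and dilutes them with off-target inserts.
Normalised expression estimates the underlying fractions because uniform
read losses (QC failures, unmapped reads) cancel in the ratio.

## Read QC

- **Quality screen**: whole-read retention at median Phred ≥ Q30. The median
  of an even-length read is the lower-middle order statistic, keeping the
  threshold integer-exact. Screening precedes trimming so that quality
  failures are attributed independently of adapter content.
- **Adapter removal**: exact substring matching — the leftmost occurrence of
  the full 3′ adapter, else the longest read-suffix equal to an adapter
  prefix of ≥ 5 nt. Trimming iterates to a fixed point, which makes the QC
  operation idempotent. Error-tolerant trimming is deliberately out of
  scope; the generator plants adapters error-free.
- **Length window**: 15–35 nt inclusive, applied after trimming (insert
  length is only meaningful post-trim).
- The QC report partitions its input exactly (reads out + median-Q failures
  + length failures = reads in); this is enforced at run time and by
  property tests.
- `N` bases pass QC and count as mismatches during mapping.

## Mapping

A sequence hits a reference entry when the shorter of the two is fully
contained in the longer at some ungapped offset with Hamming distance ≤ 1
over the overlap. Containment absorbs the 3′ length jitter of real small-RNA
reads (partial trimming, templated additions); an exact end-to-end mode is
available. Assignment is at minimal distance; ties across entries make the
sequence ambiguous, resolved by policy:

- `discard` (default): counted as unmapped, flagged — conservative, integral
  counts;
- `split`: count divided equally among tied entries (fractional counts);
- `first`: lexicographically smallest tied name.

Candidates are generated with an exact-match hash plus a pigeonhole split
(one half of the shorter sequence must match exactly if the overlap has ≤ 1
mismatch). The index is pure engineering: its contract is equality with an
exhaustive all-entries, all-offsets Hamming scan, which the test suite
checks over thousands of mutated reads for every mode, mismatch budget and
policy. Synthetic references are built with pairwise Hamming distance ≥ 3
between equal-length entries, so single-substitution reads cannot be
ambiguous at equal length by construction.

Genome pre-mapping is not performed; sequences map directly to the mature
reference.

## Quantification and filters

- Normalised expression: `100 · count / mapped_total` per sample; unfiltered
  columns sum to exactly 100.
- Detection filter: a miRNA is retained iff it has ≥ 10 reads summed over
  the cohort **and** nonzero counts in ≥ 3 subjects. The read threshold is
  read cohort-wide: a per-sample reading would contradict the existence of
  single-subject detections at low counts, which the penetrance analysis is
  about. Both thresholds are configurable.
- After filtering, columns are **not** renormalised, so abundant-species
  percentages keep their meaning as shares of all originally mapped reads
  (a renormalisation flag exists).
- Presence means count > 0, not count ≥ threshold.

## Baseline statistics

- **Load fraction**: miRNAs ranked by cohort mean expression; top-k sum over
  total. Non-decreasing in k, equal to 1 at k = n.
- **Stability**: SEM = sample SD (ddof 1)/√n; the ranking score is relative
  SEM (SEM/mean). Raw SEM would trivially favour lowly expressed species,
  whereas the stable set should span orders of expression magnitude; a raw
  SEM mode is kept as configuration. Zero-mean rows have undefined scores
  and rank last, flagged. Ties break by higher mean, then name. The stable
  set is the top ceil(10 %) of miRNAs.
- **CV comparison**: per-miRNA CV (%) across subjects, averaged within each
  set (default), or one pooled CV over all of a set's values (config). The
  set-level average is the default because the haemolysis sentinel is a
  statement about typical per-species variability, not about the pooled
  value distribution. The default blood-cell set is
  {miR-486-5p, miR-92a-3p, miR-181a-5p, miR-151a-3p, let-7f-5p}, fully
  overridable.
- **Ranges**: five-number summary with linear interpolation between order
  statistics, declared in the output metadata.

## Covariate comparisons

- Factor elimination is additive least-squares residualization: per miRNA,
  expression is regressed on the binary nuisance factors (intercept
  included) and replaced by residuals plus the grand mean. Rank-deficient
  designs fail loudly naming the collinear factors; the pipeline driver
  falls back to an unadjusted comparison with a printed warning, since small
  synthetic designs can be confounded by construction.
- The test is a per-miRNA two-sided two-sample t-test, Welch by default
  (pooled-variance mode available). Zero-variance-in-both-groups rows are
  flagged and excluded from the significant set.
- Fold change adds a pseudocount of half the smallest nonzero matrix value
  to both group means before the ratio, keeping ordering finite at zero
  means; a log2 fold change is emitted alongside.
- No multiple-testing correction by default (raw P < 0.05 calls);
  Benjamini–Hochberg adjustment is available. Expect ≈ α·n chance calls in
  the default mode.
- Heat-map export standardises each row to mean 0, SD 1 and clips to
  [−2, +2].
- BMI association is a per-miRNA Pearson correlation, optionally stratified
  by sex.

## Synthetic cohort generator

What it emulates: an 18-donor cohort (9 F / 9 M; 4 smokers per sex; 7 obese
females, 2 obese males; obese = BMI ≥ 30, configurable threshold), a
top-skewed abundance profile, between-subject lognormal abundance noise,
planted multiplicative covariate effects applied before renormalisation,
optional haemolysis spikes on a blood-cell miRNA set in chosen subjects,
TruSeq-style read anatomy (insert + 3′ adapter, 50 nt reads, Phred+33),
per-base substitution errors, a configurable off-target read fraction, and
a two-component quality model ("good" reads at Q38 everywhere, "bad" reads
at Q20 so the Q30 screen's pass set is exactly knowable).

Key defaults, with rationale:

| parameter | default | rationale |
|---|---|---|
| `n_subjects` | 18 | the emulated study design (9 F / 9 M) |
| `reads_per_subject` | 100,000 | a ~80× scale-down of a multi-million-read run that preserves the detectability of every species ≥ 0.01 % |
| `n_mirnas` | 200 | enough tail species for the detection filter and penetrance analyses to be non-trivial |
| `top1_target`, `top10_target` | 0.60, 0.90 | plasma's observed concentration: one dominant species near 60 %, top ten near 90 % |
| tail law | geometric, ratio 0.95 (auto-steepened) | spreads tail expression over several orders of magnitude while keeping rank order |
| `seq_error_rate` | 0.005/base | typical short-read substitution scale |
| `noise_read_fraction` | 0.10 | degradation/off-target inserts that pass QC but do not map |
| `low_quality_fraction` | 0.05 | reads planted to fail the Q30 screen |
| `biological_cv` | 0.15 | see below |
| `adapter` | TruSeq small-RNA 3′ adapter | standard library chemistry |

**Biological CV.** The default between-subject CV of per-miRNA abundance is
0.15. This is a deliberate calibration: it represents the biological
component of variation in a well-controlled disease-free cohort, and keeps
the cohort-level abundance structure identifiable at n = 18 (the dominant
species' fraction is then estimated with standard error ≈ 0.01, and
renormalisation bias — about −0.29·σ²/2 on the top fraction — stays below
0.005). Real plasma cohorts show much larger per-miRNA CVs (around
100 %), but a substantial share of that is pre-analytical (haemolysis,
centrifugation differences), which the generator models separately through
the haemolysis spike rather than folding it into the biological term.
Power simulations that need heavier noise (e.g. the differential-expression
acceptance runs at CV 30 %) set it explicitly.

What the generator does **not** model: ligation bias, PCR duplicates/UMIs,
isomiR ground truth beyond what containment mapping absorbs, genome-level
background reads, adapter sequencing errors, and per-subject depth
variation. Passing recovery tests therefore demonstrate correctness of the
analysis chain under these idealisations, not robustness to the full
pre-analytical variability of real plasma data.

## Numerical choices

- Even-length median: lower-middle order statistic.
- Tally serialisation: descending count, ties lexicographic — reproducible
  files.
- Reference generation: rejection sampling with an explicit attempt budget;
  impossible requests fail with a message rather than looping.
- Degenerate profile targets (top1 = top10) force ranks 2–10 to zero mass;
  the tail monotonicity constraint is waived in that case, which is the only
  consistent reading.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; cohort outputs are byte-identical
  across reruns.
- Quartiles: linear interpolation (`numpy.percentile` default), stated in
  output headers.
- Pipeline artifacts are stamped with a config hash; stages resume only when
  the hash matches, and a resumed run is bit-identical to a fresh one.

## Problem sizes

The bundled analysis scripts run 18 subjects × 20,000 reads; the acceptance
script and the recovery tests run 18 × 100,000 reads with 200 reference
miRNAs, 500 differential-expression simulations at n = 9 vs 9, a
1,000-miRNA null panel, and 20 reference/read-set instances for the mapper
oracle. These sizes were chosen so that every statistical check is
well-powered while a complete validation pass stays in the minutes range on
a single CPU.

## Known limitations

- Adapter trimming is exact-match only; error-containing adapters would
  escape it (and are not generated).
- The mapper handles substitutions only — no indels, no gapped alignment,
  no novel-miRNA discovery.
- Factor elimination by linear residualization is one standard reading of
  "removing contributions from other factors"; other adjustment schemes
  (e.g. stratification) would give different small-sample behaviour.
- With 18 subjects, unadjusted P < 0.05 calls include false positives at
  roughly the α·n rate; the Benjamini–Hochberg option exists precisely
  because candidate lists from such cohorts need external validation.
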