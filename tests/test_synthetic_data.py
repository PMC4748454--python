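import gzip
import itertools

import numpy as np
import pandas as pd
import pytest

from mirnaome.read_qc import qc_filter
from mirnaome.synthetic_data import (
    AbundanceProfile,
    CohortConfig,
    CohortTruth,
    HaemolysisSpike,
    PlantedEffect,
    make_metadata,
    make_reference,
    realized_abundance,
    sample_profile,
    simulate_cohort,
    simulate_subject,
)
from mirnaome.tally import build_tally

META_F = pd.Series({"sex": "F", "smoking": "yes", "bmi": 33.0, "obese": True}, name="FA01")
META_M = pd.Series({"sex": "M", "smoking": "no", "bmi": 24.0, "obese": False}, name="MA01")


class TestMakeReference:
    def test_degenerate_single_entry(self):
        ref = make_reference(1, (22, 22), rng_seed=7)
        assert len(ref) == 1
        assert len(next(iter(ref.entries.values()))) == 22

    def test_pairwise_hamming_distance_at_least_3(self):
        """All-pairs scan over a 200-entry reference."""
        ref = make_reference(200, (18, 25), rng_seed=1)
        assert len(ref) == 200
        seqs = list(ref.entries.values())
        for a, b in itertools.combinations(seqs, 2):
            if len(a) == len(b):
                assert sum(x != y for x, y in zip(a, b)) >= 3

    def test_deterministic_fasta_bytes(self, tmp_path):
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        make_reference(50, (18, 25), rng_seed=9).to_fasta(p1)
        make_reference(50, (18, 25), rng_seed=9).to_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_exhausted_placement_budget_fails_explicitly(self):
        with pytest.raises(ValueError, match="attempts"):
            make_reference(1000, (15, 15), rng_seed=0, max_attempts=5)
        with pytest.raises(ValueError, match="length_range"):
            make_reference(5, (10, 12), rng_seed=0)


class TestSampleProfile:
    def test_targets_hit_exactly(self):
        ref = make_reference(200, (18, 25), rng_seed=1)
        profile = sample_profile(ref, 0.60, 0.90, rng_seed=2)
        s = profile.sorted_fractions()
        assert s.iloc[0] == pytest.approx(0.60, abs=1e-6)
        assert s.iloc[:10].sum() == pytest.approx(0.90, abs=1e-6)
        assert profile.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_equal_targets_zero_ranks_2_to_10(self):
        ref = make_reference(30, (18, 25), rng_seed=1)
        profile = sample_profile(ref, 0.5, 0.5, rng_seed=0)
        assert profile.fractions.max() == pytest.approx(0.5)
        assert (profile.fractions.values == 0).sum() == 9  # ranks 2-10 empty
        assert profile.fractions.sum() == pytest.approx(1.0)

    def test_tail_fractions_non_increasing(self):
        ref = make_reference(120, (18, 25), rng_seed=4)
        profile = sample_profile(ref, 0.60, 0.90, rng_seed=4)
        ranked = np.sort(profile.fractions.values)[::-1]
        assert (np.diff(ranked) <= 1e-12).all()
        # several orders of magnitude across the tail
        tail = ranked[10:]
        assert tail[0] / tail[-1] > 100

    def test_infeasible_targets_rejected(self):
        ref = make_reference(30, (18, 25), rng_seed=1)
        with pytest.raises(ValueError):
            sample_profile(ref, 0.9, 0.5, rng_seed=0)
        with pytest.raises(ValueError):
            sample_profile(ref, 0.01, 0.999, rng_seed=0)  # rank-2 > top1


class TestRealizedAbundance:
    def config(self, **kw):
        base = dict(n_subjects=2, n_mirnas=30, biological_cv=0.0, rng_seed=0)
        base.update(kw)
        return CohortConfig(**base)

    def profile(self, ref):
        return sample_profile(ref, 0.4, 0.8, rng_seed=1)

    def test_planted_fold_applies_before_renormalization(self):
        ref = make_reference(30, (18, 25), 0)
        profile = self.profile(ref)
        m = profile.fractions.idxmax()
        config = self.config(planted_effects=[PlantedEffect(m, "smoking", 4.0)])
        rng = np.random.default_rng(0)
        smoker = realized_abundance(profile, config, META_F, rng)
        base = profile.fractions
        expected = 4 * base[m] / (1 + 3 * base[m])
        assert smoker[m] == pytest.approx(expected)
        nonsmoker = realized_abundance(profile, config, META_M, np.random.default_rng(0))
        assert nonsmoker[m] == pytest.approx(base[m])

    def test_haemolysis_spike_multiplies_before_renormalization(self):
        ref = make_reference(30, (18, 25), 0)
        profile = self.profile(ref)
        spiked_set = tuple(profile.fractions.nlargest(2).index)
        config = self.config(
            haemolysis_spike=HaemolysisSpike("FA01", spiked_set, 10.0))
        x = profile.fractions.copy()
        for m in spiked_set:
            x[m] *= 10
        expected = x / x.sum()
        got = realized_abundance(profile, config, META_F, np.random.default_rng(0))
        assert np.allclose(got.values, expected.values)

    def test_biological_cv_zero_reproduces_profile(self):
        ref = make_reference(30, (18, 25), 0)
        profile = self.profile(ref)
        got = realized_abundance(profile, self.config(), META_M, np.random.default_rng(5))
        assert np.allclose(got.values, profile.fractions.values)


class TestSimulateSubject:
    def test_no_noise_limit_reproduces_reference_insert(self):
        ref = make_reference(1, (22, 22), 7)
        profile = AbundanceProfile(pd.Series({next(iter(ref.entries)): 1.0}))
        config = CohortConfig(
            n_subjects=2, reads_per_subject=100, n_mirnas=1,
            mirna_length_range=(22, 22), seq_error_rate=0.0,
            noise_read_fraction=0.0, low_quality_fraction=0.0, rng_seed=0,
        )
        reads, abund = simulate_subject(ref, profile, config, META_M, 3)
        insert = next(iter(ref.entries.values()))
        assert len(reads) == 100
        clean, _ = qc_filter(reads, config.adapter)
        assert all(r.sequence == insert for r in clean)

    def test_error_rate_matches_binomial_expectation(self):
        """Fraction of inserts carrying >= 1 substitution ~ 1-(1-p)^L."""
        ref = make_reference(1, (22, 22), 7)
        insert = next(iter(ref.entries.values()))
        profile = AbundanceProfile(pd.Series({next(iter(ref.entries)): 1.0}))
        p = 0.01
        config = CohortConfig(
            n_subjects=2, reads_per_subject=10_000, n_mirnas=1,
            mirna_length_range=(22, 22), seq_error_rate=p,
            noise_read_fraction=0.0, low_quality_fraction=0.0, rng_seed=0,
        )
        reads, _ = simulate_subject(ref, profile, config, META_M, 11)
        clean, _ = qc_filter(reads, config.adapter)
        frac = np.mean([r.sequence != insert for r in clean])
        expected = 1 - (1 - p) ** len(insert)
        sd = np.sqrt(expected * (1 - expected) / len(clean))
        assert abs(frac - expected) < 3 * sd

    def test_insert_composition_matches_truth_within_multinomial_error(self):
        ref = make_reference(20, (20, 24), 5)
        profile = sample_profile(ref, 0.5, 0.9, rng_seed=5)
        config = CohortConfig(
            n_subjects=2, reads_per_subject=20_000, n_mirnas=20,
            seq_error_rate=0.0, noise_read_fraction=0.0,
            low_quality_fraction=0.0, biological_cv=0.2, rng_seed=0,
        )
        reads, truth_abund = simulate_subject(ref, profile, config, META_F, 13)
        clean, _ = qc_filter(reads, config.adapter)
        tally = build_tally(clean, "s")
        n = tally.total
        z_scores = []
        for name, seq in ref.entries.items():
            observed = tally.entries.get(seq, 0)
            expect = n * truth_abund[name]
            sd = np.sqrt(max(expect * (1 - truth_abund[name]), 1.0))
            z_scores.append(abs(observed - expect) / sd)
        # per-species 3 SD with a multiplicity allowance: across 20 species a
        # single ~3 SD excursion is expected by chance, beyond 4 SD is not
        assert sum(z > 3 for z in z_scores) <= 1
        assert max(z_scores) < 4


class TestSimulateCohort:
    def test_metadata_covariate_balance_as_configured(self):
        config = CohortConfig(n_subjects=18, rng_seed=6)
        meta = make_metadata(config, np.random.default_rng(6))
        assert meta["sex"].value_counts().to_dict() == {"F": 9, "M": 9}
        assert (meta.groupby("sex")["smoking"].apply(lambda s: (s == "yes").sum())
                .to_dict() == {"F": 4, "M": 4})
        assert meta.groupby("sex")["obese"].sum().to_dict() == {"F": 7, "M": 2}
        assert ((meta["bmi"] >= 30) == meta["obese"]).all()

    def test_rerun_with_same_seed_is_byte_identical(self, tmp_path):
        config = CohortConfig(n_subjects=3, reads_per_subject=500,
                              n_mirnas=20, rng_seed=12)
        a = simulate_cohort(config, tmp_path / "a")
        b = simulate_cohort(config, tmp_path / "b")
        for name in ("reference.fasta", "metadata.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()
        for sid in a.fastq_paths:
            assert gzip.open(a.fastq_paths[sid]).read() == \
                gzip.open(b.fastq_paths[sid]).read()

    def test_existing_output_dir_requires_overwrite(self, tmp_path):
        config = CohortConfig(n_subjects=2, reads_per_subject=50,
                              n_mirnas=30, rng_seed=0)
        simulate_cohort(config, tmp_path / "out")
        with pytest.raises(FileExistsError):
            simulate_cohort(config, tmp_path / "out")
        simulate_cohort(config, tmp_path / "out", overwrite=True)

    def test_truth_round_trips_through_json(self, tmp_path):
        config = CohortConfig(
            n_subjects=2, reads_per_subject=50, n_mirnas=30, rng_seed=0,
            planted_effects=[PlantedEffect("syn-miR-01", "sex", 2.0)],
        )
        cohort = simulate_cohort(config, tmp_path / "out")
        loaded = CohortTruth.from_json(tmp_path / "out" / "truth.json")
        assert loaded.planted_effects == cohort.truth.planted_effects
        assert np.allclose(
            loaded.abundances[cohort.truth.abundances.columns].values,
            cohort.truth.abundances.values, atol=1e-9,
        )
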