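"""Synthetic-data generator: determinism, distributional and ground-truth checks."""

import numpy as np
import pytest

import rohmix
from rohmix.simulate import (
    CrossDesign,
    gen_autozygous_genomes,
    gen_breed_frequencies,
    gen_cross_genotypes,
    gen_marker_map,
    gen_purebred_genotypes,
)
from rohmix.genotypes import MISSING
from rohmix.qc import hwe_chisq_pvalues


class TestMarkerMap:
    def test_uniform_spacing(self):
        mm = gen_marker_map(1, 100, 10_000_000, "uniform", seed=0)
        d = np.diff(mm.position)
        assert 95_000 < d.mean() < 105_000
        assert mm.position[0] >= 1 and mm.position[-1] <= 10_000_000

    def test_c12k_panel_scale(self):
        mm = gen_marker_map(18, 650, 125_000_000, "uniform", seed=0)
        assert len(mm) == 11_700  # emulates an ~11.7K autosomal panel
        assert list(mm.chromosomes) == list(range(1, 19))

    @pytest.mark.parametrize("spacing", ["uniform", "jittered"])
    def test_same_seed_identical(self, spacing):
        a = gen_marker_map(3, 50, 5_000_000, spacing, seed=42)
        b = gen_marker_map(3, 50, 5_000_000, spacing, seed=42)
        assert np.array_equal(a.position, b.position)
        assert np.array_equal(a.snp_id, b.snp_id)

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            gen_marker_map(0, 10)
        with pytest.raises(ValueError):
            gen_marker_map(1, 1)


class TestBreedFrequencies:
    def test_no_drift_limit_rows_equal(self):
        mm = gen_marker_map(1, 200, 10_000_000, seed=1)
        tree = (0.0, [(0.0, "A"), (0.0, [(0.0, "B"), (0.0, "C")])])
        ft = gen_breed_frequencies(mm, tree, seed=5)
        assert np.array_equal(ft.row("A"), ft.row("B"))
        assert np.array_equal(ft.row("B"), ft.row("C"))

    def test_within_cluster_correlation_exceeds_cross(self):
        mm = gen_marker_map(1, 2000, 20_000_000, seed=1)
        tree = (0.0, [(0.3, [(0.02, "A"), (0.02, "B")]), (0.3, [(0.02, "C")])])
        within, cross = [], []
        for seed in range(10):
            ft = gen_breed_frequencies(mm, tree, seed=seed)
            r = np.corrcoef(ft.freq)
            i, j, k = (ft.breeds.index(x) for x in "ABC")
            within.append(r[i, j])
            cross.append(r[i, k])
        assert np.mean(within) > np.mean(cross)
        assert all(w > c for w, c in zip(within, cross))

    def test_frequencies_in_unit_interval(self, map5k, freqs5k):
        assert freqs5k.freq.min() >= 0.0 and freqs5k.freq.max() <= 1.0
        assert freqs5k.n_snps == len(map5k)

    def test_same_seed_identical(self, map5k):
        a = gen_breed_frequencies(map5k, seed=3)
        b = gen_breed_frequencies(map5k, seed=3)
        assert np.array_equal(a.freq, b.freq)


class TestPurebredGenotypes:
    def test_degenerate_frequencies(self):
        mm = gen_marker_map(1, 10, 1_000_000, seed=0)
        ones = gen_purebred_genotypes(mm, np.ones(10), 20, seed=1)
        assert np.all(ones.dosage == 2)
        zeros = gen_purebred_genotypes(mm, np.zeros(10), 20, seed=1)
        assert np.all(zeros.dosage == 0)

    def test_realized_frequency_binomial_se(self):
        mm = gen_marker_map(1, 300, 30_000_000, seed=0)
        rng = np.random.default_rng(7)
        x = rng.uniform(0.1, 0.9, 300)
        gm = gen_purebred_genotypes(mm, x, 500, seed=8)
        realized = gm.dosage.mean(axis=0) / 2
        se = np.sqrt(x * (1 - x) / (2 * 500))
        within = np.abs(realized - x) <= 3 * se
        assert within.mean() >= 0.99  # 3-SE band holds for ~99.7% of SNPs

    def test_missingness(self):
        mm = gen_marker_map(1, 500, 10_000_000, seed=0)
        clean = gen_purebred_genotypes(mm, np.full(500, 0.5), 50, missing_rate=0.0, seed=2)
        assert not clean.missing_mask().any()
        dirty = gen_purebred_genotypes(mm, np.full(500, 0.5), 50, missing_rate=0.1, seed=2)
        assert 0.08 < dirty.missing_mask().mean() < 0.12

    def test_frequency_row_length_mismatch(self):
        mm = gen_marker_map(1, 10, 1_000_000, seed=0)
        with pytest.raises(ValueError):
            gen_purebred_genotypes(mm, np.full(11, 0.5), 5)

    def test_hwe_holds_at_nominal_rate(self):
        mm = gen_marker_map(1, 1000, 50_000_000, seed=0)
        rng = np.random.default_rng(9)
        x = rng.uniform(0.1, 0.9, 1000)
        gm = gen_purebred_genotypes(mm, x, 200, seed=10)
        p = hwe_chisq_pvalues(gm.dosage)
        reject = (p < 0.05).mean()
        assert 0.03 < reject < 0.075  # ~nominal 5% ± Monte-Carlo error


class TestCrossGenotypes:
    def test_f1_origin_exactly_half(self, map5k, freqs5k):
        d = CrossDesign("DC", "NX", "F1")
        _, realized = gen_cross_genotypes(
            map5k, freqs5k.row("DC"), freqs5k.row("NX"), d, 5, seed=1
        )
        assert np.all(realized == 0.5)

    def test_backcross_origin_within_binomial_se(self, map5k, freqs5k):
        m = len(map5k)
        d = CrossDesign("DC", "NX", "BC_A")
        _, realized = gen_cross_genotypes(
            map5k, freqs5k.row("DC"), freqs5k.row("NX"), d, 5, seed=2
        )
        se = np.sqrt(0.75 * 0.25 / (2 * m))
        assert np.all(np.abs(realized - 0.75) <= 3 * se)

    def test_f2_heterozygosity_matches_expectation(self, map5k, freqs5k):
        # oracle: alleles drawn independently with marginal frequency
        # q = (pA + pB)/2, so E[het] = mean over SNPs of 2 q (1 − q)
        pa, pb = freqs5k.row("DC"), freqs5k.row("NX")
        q = (pa + pb) / 2
        expected = float(np.mean(2 * q * (1 - q)))
        d = CrossDesign("DC", "NX", "F2")
        gm, _ = gen_cross_genotypes(map5k, pa, pb, d, 20, seed=3)
        observed = (gm.dosage == 1).mean()
        se = np.sqrt(expected * (1 - expected) / gm.dosage.size)
        assert abs(observed - expected) <= 4 * se

    def test_unknown_cross_type_rejected(self):
        with pytest.raises(ValueError):
            CrossDesign("A", "B", "F3")

    def test_expected_proportions(self):
        assert CrossDesign("A", "B", "F1").expected_proportions == (0.5, 0.5)
        assert CrossDesign("A", "B", "BC_A").expected_proportions == (0.75, 0.25)
        assert CrossDesign("A", "B", "BC_B").expected_proportions == (0.25, 0.75)


class TestAutozygousGenomes:
    def test_target_zero_empty_truth(self, dense_map):
        _, truth = gen_autozygous_genomes(
            dense_map, np.full(len(dense_map), 0.5), 3, 0.0, seed=1
        )
        assert len(truth) == 0

    def test_coverage_near_target(self):
        mm = rohmix.gen_marker_map(18, 100, 125_000_000, "uniform", seed=4)
        lengths = {c: 125_000_000 for c in range(1, 19)}  # 2,250 Mb genome
        _, truth = gen_autozygous_genomes(
            mm, np.full(len(mm), 0.5), 10, 0.10, mean_seg_len_mb=5.0,
            seed=5, chrom_lengths=lengths,
        )
        per_animal = truth.total_length_per_animal([f"auto{i+1}" for i in range(10)])
        coverage = per_animal.to_numpy() / 2_250_000_000
        assert abs(coverage.mean() - 0.10) <= 0.01

    def test_segment_lengths_exponential_mean(self):
        mm = rohmix.gen_marker_map(18, 100, 125_000_000, "uniform", seed=4)
        lengths = {c: 125_000_000 for c in range(1, 19)}
        _, truth = gen_autozygous_genomes(
            mm, np.full(len(mm), 0.5), 8, 0.10, mean_seg_len_mb=5.0,
            seed=6, chrom_lengths=lengths,
        )
        lens_mb = truth.lengths() / 1e6
        assert len(lens_mb) >= 200
        se = 5.0 / np.sqrt(len(lens_mb))  # exponential: sd = mean
        assert abs(lens_mb.mean() - 5.0) <= 3 * se

    def test_planted_intervals_fully_homozygous(self, dense_map):
        rng = np.random.default_rng(14)
        base = rng.uniform(0.2, 0.8, len(dense_map))
        gm, truth = gen_autozygous_genomes(
            dense_map, base, 4, 0.15, mean_seg_len_mb=4.0, seed=7, missing_rate=0.0
        )
        ids = list(gm.animal_ids)
        for row in truth.segments.itertuples():
            i = ids.index(row.animal)
            s = dense_map.chrom_slice(row.chromosome)
            pos = dense_map.position[s]
            inside = (pos >= row.start) & (pos <= row.end)
            g = gm.dosage[i, s][inside]
            assert np.all((g == 0) | (g == 2))

    def test_unreachable_target_reports_shortfall(self):
        mm = evenly = rohmix.gen_marker_map(1, 10, 2_000_000, seed=1)
        with pytest.raises(RuntimeError, match="shortfall"):
            gen_autozygous_genomes(
                mm, np.full(10, 0.5), 1, 0.5, mean_seg_len_mb=50.0, seed=2,
                min_seg_len_mb=10.0, max_attempts_per_segment=50,
            )

    def test_same_seed_identical(self, dense_map):
        kw = dict(n_animals=2, target_f=0.05, mean_seg_len_mb=4.0, seed=9)
        a_gm, a_truth = gen_autozygous_genomes(dense_map, np.full(len(dense_map), 0.5), **kw)
        b_gm, b_truth = gen_autozygous_genomes(dense_map, np.full(len(dense_map), 0.5), **kw)
        assert np.array_equal(a_gm.dosage, b_gm.dosage)
        assert a_truth.segments.equals(b_truth.segments)
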