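"""Admixture GBC: likelihood, optimizer, filters, classification, change point."""

import itertools
import math

import numpy as np
import pytest

import rohmix
from rohmix.gbc import (
    ChangePoint,
    admixture_loglik,
    classify_purebred,
    estimate_gbc,
    gbc_change_point,
    genotype_prob,
    mixture_freq,
    nullify_rescale,
    two_breed_composition,
)
from rohmix.simulate import CrossDesign


def grid_search_loglik(g_vec, freq, resolution=0.01):
    """Exhaustive simplex grid oracle: best (weights, loglik) at a resolution."""
    t = freq.shape[0]
    steps = int(round(1 / resolution))
    best_w, best_ll = None, -np.inf
    for combo in itertools.product(range(steps + 1), repeat=t - 1):
        if sum(combo) > steps:
            continue
        w = np.array(list(combo) + [steps - sum(combo)]) / steps
        ll = admixture_loglik(g_vec, freq, w)
        if ll > best_ll:
            best_w, best_ll = w, ll
    return best_w, best_ll


class TestGenotypeProb:
    @pytest.mark.parametrize(
        "g,f,expected", [(1, 0.5, 0.5), (0, 0.0, 1.0), (2, 0.3, 0.09), (0, 0.4, 0.36)]
    )
    def test_values(self, g, f, expected):
        assert genotype_prob(g, f) == pytest.approx(expected)

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            genotype_prob(-1, 0.5)


class TestMixtureFreq:
    def test_values(self):
        assert mixture_freq(np.array([1.0, 0.0]), np.array([0.4, 0.9])) == pytest.approx(0.4)
        assert mixture_freq(np.array([0.5, 0.5]), np.array([0.2, 0.6])) == pytest.approx(0.4)

    def test_convexity_constant_columns(self):
        x = np.full(3, 0.37)
        for w in ([1, 0, 0], [0.2, 0.3, 0.5]):
            assert mixture_freq(np.array(w, float), x) == pytest.approx(0.37)


class TestLoglik:
    def test_single_het_snp_at_half(self):
        # ln Pr(g=1 | f=0.5) = ln(2·0.5·0.5) = ln 0.5
        ll = admixture_loglik(np.array([1]), np.array([[0.5]]), np.array([1.0]))
        assert ll == pytest.approx(math.log(0.5))

    def test_duplicated_snp_doubles_contribution(self):
        g1, x1 = np.array([2]), np.array([[0.3], [0.8]])
        g2, x2 = np.array([2, 2]), np.array([[0.3, 0.3], [0.8, 0.8]])
        w = np.array([0.4, 0.6])
        assert admixture_loglik(g2, x2, w) == pytest.approx(2 * admixture_loglik(g1, x1, w))

    def test_matches_direct_product_form(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            m, t = 50, 3
            x = rng.uniform(0.05, 0.95, size=(t, m))
            w = rng.dirichlet(np.ones(t))
            g = rng.integers(0, 3, size=m)
            direct = sum(
                math.log(genotype_prob(int(gk), float(w @ x[:, k])))
                for k, gk in enumerate(g)
            )
            assert admixture_loglik(g, x, w) == pytest.approx(direct, abs=1e-10)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            admixture_loglik(np.array([-1, -1]), np.array([[0.5, 0.5]]), np.array([1.0]))


class TestEstimateGBC:
    def test_single_breed_is_trivial(self):
        g = np.array([0, 1, 2, 1])
        res = estimate_gbc(g, np.array([[0.2, 0.4, 0.9, 0.5]]), breeds=["X"])
        assert res.weights == pytest.approx([1.0])
        assert res.converged

    def test_purebred_recovery_well_separated(self):
        rng = np.random.default_rng(32)
        m = 2000
        x = np.vstack([rng.uniform(0.05, 0.3, m), rng.uniform(0.7, 0.95, m)])
        g = rng.binomial(2, x[1])
        res = estimate_gbc(g, x, breeds=["low", "high"])
        assert res.weight_of("high") >= 0.99

    def test_f1_recovery(self, map5k, freqs5k):
        d = CrossDesign("DC", "NX", "F1")
        gm, _ = rohmix.gen_cross_genotypes(
            map5k, freqs5k.row("DC"), freqs5k.row("NX"), d, 1, seed=33
        )
        res = estimate_gbc(gm.dosage[0], freqs5k, nullify_threshold=0.01)
        assert abs(res.weight_of("DC") - 0.5) <= 0.05
        assert abs(res.weight_of("NX") - 0.5) <= 0.05

    def test_grid_oracle_equivalence_t2_t3(self):
        rng = np.random.default_rng(34)
        for t in (2, 3):
            m = 300
            x = rng.uniform(0.05, 0.95, size=(t, m))
            w_true = rng.dirichlet(np.ones(t))
            g = rng.binomial(2, w_true @ x)
            res = estimate_gbc(g, x, nullify_threshold=0.0, prune_tol=0.0)
            w_grid, ll_grid = grid_search_loglik(g, x, resolution=0.02)
            assert res.loglik >= ll_grid - 1e-9
            assert np.max(np.abs(res.raw_weights - w_grid)) <= 0.02 + 1e-9

    def test_likelihood_ascent_from_uniform(self, map5k, freqs5k):
        gm = rohmix.gen_purebred_genotypes(map5k, freqs5k.row("EH"), 1, seed=35)
        g = gm.dosage[0]
        uniform = np.full(freqs5k.n_breeds, 1 / freqs5k.n_breeds)
        res = estimate_gbc(g, freqs5k)
        assert res.loglik >= admixture_loglik(g, freqs5k.freq, uniform)


class TestNullifyRescale:
    def test_small_component_zeroed(self):
        out = nullify_rescale(np.array([0.995, 0.005]), 0.01)
        assert out == pytest.approx([1.0, 0.0])

    def test_balanced_unchanged(self):
        out = nullify_rescale(np.array([0.5, 0.5]), 0.01)
        assert out == pytest.approx([0.5, 0.5])

    def test_renormalization(self):
        out = nullify_rescale(np.array([0.90, 0.06, 0.04]), 0.05)
        assert out == pytest.approx([0.9375, 0.0625, 0.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            nullify_rescale(np.array([0.4, 0.6]), 0.7)

    def test_sums_to_one_nonnegative(self):
        rng = np.random.default_rng(36)
        for _ in range(20):
            w = rng.dirichlet(np.ones(6))
            out = nullify_rescale(w, 0.05)
            assert out.sum() == pytest.approx(1.0, abs=1e-8)
            assert np.all(out >= 0)


class TestClassification:
    def make_result(self, weights, breeds):
        return rohmix.GBCResult("a", list(breeds), np.array(weights),
                                np.array(weights), 0.0, True)

    def test_boundary_inclusive(self):
        res = self.make_result([0.94, 0.06], ["NX", "DC"])
        assert classify_purebred(res, "NX", 0.94) == "purebred"
        res2 = self.make_result([0.93, 0.07], ["NX", "DC"])
        assert classify_purebred(res2, "NX", 0.94) == "crossbred"

    def test_perfect_cutoff(self):
        res = self.make_result([1.0, 0.0], ["NX", "DC"])
        assert classify_purebred(res, "NX", 1.0) == "purebred"

    def test_unknown_breed(self):
        with pytest.raises(KeyError):
            classify_purebred(self.make_result([1.0], ["NX"]), "ZZ")


class TestTwoBreedComposition:
    BREEDS = ["DC", "NX", "LR"]

    def test_rescaling(self):
        pair = two_breed_composition(np.array([0.32, 0.64, 0.04]), self.BREEDS, "DC", "NX")
        assert pair == pytest.approx((1 / 3, 2 / 3))

    def test_pure_animal_rejected(self):
        assert two_breed_composition(np.array([0.0, 1.0, 0.0]), self.BREEDS, "DC", "NX") is None

    def test_third_breed_survivor_rejected(self):
        assert two_breed_composition(np.array([0.45, 0.45, 0.10]), self.BREEDS, "DC", "NX") is None

    def test_f1_simulation_near_half(self, map5k, freqs5k):
        d = CrossDesign("DC", "NX", "F1")
        gm, _ = rohmix.gen_cross_genotypes(
            map5k, freqs5k.row("DC"), freqs5k.row("NX"), d, 3, seed=37
        )
        for i in range(3):
            res = estimate_gbc(gm.dosage[i], freqs5k)
            pair = two_breed_composition(res.weights, res.breeds, "DC", "NX")
            assert pair is not None
            assert 0.16 <= pair[0] <= 0.62  # observed crossbred envelope
            assert abs(pair[0] - 0.5) <= 0.10


class TestPanelSizeStringency:
    def test_exact_purity_calls_non_increasing_in_panel_size(self):
        """Larger panels have more power to flag low-level admixture, so the
        count of animals at exactly 1.0 for the true breed cannot grow."""
        from rohmix.qc import uniform_panel_select

        mm = rohmix.gen_marker_map(18, 650, 125_000_000, "uniform", seed=5)
        _, idx1k = uniform_panel_select(mm, 1000)
        _, idx5k = uniform_panel_select(mm, 5000)
        panels = [idx1k, idx5k, np.arange(len(mm))]
        counts = [0, 0, 0]
        admix = [0.0] * 2 + [0.02] * 8  # mostly 2% admixed animals
        for seed in range(3):
            ft = rohmix.gen_breed_frequencies(mm, seed=60 + seed)
            rng = np.random.default_rng(80 + seed)
            for a in admix:
                p = (1 - a) * ft.row("NX") + a * ft.row("DC")
                g = rng.binomial(2, p).astype(np.int8)
                for j, idx in enumerate(panels):
                    res = estimate_gbc(g[idx], ft.freq[:, idx], breeds=ft.breeds, seed=0)
                    counts[j] += res.weight_of("NX") == 1.0
        assert counts[0] >= counts[1] >= counts[2]


def brute_force_breakpoint(v):
    """Oracle: try every single breakpoint, minimize total SSE."""
    n = len(v)
    best_k, best_sse = None, np.inf
    for k in range(1, n):
        sse = np.var(v[:k]) * k + np.var(v[k:]) * (n - k)
        if sse < best_sse:
            best_k, best_sse = k, sse
    return best_k


class TestChangePoint:
    def test_exact_step(self):
        v = np.sort(np.concatenate([np.full(100, 0.4), np.full(100, 1.0)]))
        cp = gbc_change_point(v)
        assert cp.index == 100
        assert cp.value == pytest.approx(1.0)

    def test_constant_sequence_none(self):
        assert gbc_change_point(np.full(50, 0.8)) is None

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            gbc_change_point(np.linspace(0, 1, 5))

    def test_noisy_two_regime_matches_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            tail = rng.normal(0.55, 0.04, 40)  # crossbred regime
            plateau = 1.0 - np.abs(rng.normal(0, 0.004, 160))
            v = np.sort(np.concatenate([tail, plateau]))
            cp = gbc_change_point(v)
            assert cp.index == brute_force_breakpoint(v)
            assert abs(cp.index - 40) <= 2  # within 2 ranks of the construction
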