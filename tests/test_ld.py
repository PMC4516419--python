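import numpy as np
import pytest

from radpop.ld import (
    em_haplotype_freqs,
    pairwise_r2,
    r2_composite,
    r2_em,
    r2_from_haplotypes,
    smooth_decay,
)
from radpop.matrix import GenotypeMatrix, LocusCatalog

from conftest import make_matrix
from oracles import all_genotype_tables, grid_mle_r2


class TestR2:
    def test_identical_genotype_columns_give_one(self):
        g = np.array([0, 1, 2, 0, 1, 2, 2, 0])
        assert r2_em(g, g) == pytest.approx(1.0)

    def test_phased_counts_perfect_coupling(self):
        # haplotypes AB x2, ab x2 carried by two homozygous individuals
        g1 = np.array([2, 0])
        g2 = np.array([2, 0])
        assert r2_em(g1, g2) == pytest.approx(1.0)

    def test_phased_counts_equilibrium(self):
        # gametes AB/Ab/aB/ab once each: D = 0
        g1 = np.array([2, 0])  # ind1 = AB/Ab, ind2 = aB/ab
        g2 = np.array([1, 1])
        assert r2_em(g1, g2) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_in_snp_order_and_relabel(self):
        rng = np.random.default_rng(8)
        g1 = rng.integers(0, 3, 8)
        g2 = rng.integers(0, 3, 8)
        if len(set(g1)) == 1 or len(set(g2)) == 1:
            pytest.skip("degenerate draw")
        base = r2_em(g1, g2)
        assert r2_em(g2, g1) == pytest.approx(base, abs=1e-9)
        assert r2_em(2 - g1, g2) == pytest.approx(base, abs=1e-9)

    def test_em_frequencies_preserve_margins(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            g1 = rng.integers(0, 3, 10)
            g2 = rng.integers(0, 3, 10)
            h = em_haplotype_freqs(g1, g2)
            assert h.sum() == pytest.approx(1.0, abs=1e-9)
            assert h[0] + h[1] == pytest.approx(g1.mean() / 2, abs=1e-9)
            assert h[0] + h[2] == pytest.approx(g2.mean() / 2, abs=1e-9)

    def test_em_matches_grid_oracle_small_tables(self):
        """EM r^2 equals exhaustive-likelihood profiling on every genotype
        table with n <= 5 (the full n <= 8 sweep runs in the acceptance
        suite)."""
        checked = 0
        for table in all_genotype_tables(5):
            oracle = grid_mle_r2(table)
            if np.isnan(oracle):
                continue
            g1, g2 = [], []
            for i in range(3):
                for j in range(3):
                    g1 += [i] * table[i, j]
                    g2 += [j] * table[i, j]
            r2 = r2_from_haplotypes(em_haplotype_freqs(np.array(g1), np.array(g2)))
            assert r2 == pytest.approx(oracle, abs=1e-6)
            checked += 1
        assert checked > 1000


class TestPairwiseR2:
    def test_subsample_larger_than_population_rejected(self, colony_data):
        with pytest.raises(ValueError, match="Midway"):
            pairwise_r2(
                colony_data["sparse"], colony_data["catalog"], "Midway", k_subsample=12
            )

    def test_distances_are_offset_differences(self, colony_data):
        res = pairwise_r2(
            colony_data["sparse"], colony_data["catalog"], "Tern", k_subsample=8, seed=4
        )
        for locus, o1, o2, dist, r2 in res.records:
            assert dist == abs(o2 - o1) >= 1
            assert 0.0 <= r2 <= 1.0 + 1e-9

    def test_within_locus_ld_elevated_over_unlinked_baseline(self, colony_data):
        """SNPs sharing a genealogy show strong LD; SNPs on independent loci
        show only the sampling-noise floor.  (Without intra-locus
        recombination the within-locus level carries no distance trend; the
        decay seen in real RAD data needs historical recombination, which
        the generator deliberately omits.)"""
        matrix, catalog = colony_data["complete"], colony_data["catalog"]
        res = pairwise_r2(matrix, catalog, "Tern", k_subsample=8, seed=21)
        within = res.pairs[:, 1]
        # unlinked baseline: r^2 between SNPs drawn from different loci
        rng = np.random.default_rng(33)
        rows = rng.choice(matrix.population_indices("Tern"), 8, replace=False)
        loci = np.array([l for l, _ in matrix.snp_ids])
        between = []
        while len(between) < 150:
            j1, j2 = rng.integers(0, matrix.n_snps, 2)
            if loci[j1] == loci[j2]:
                continue
            g1 = matrix.genotypes[rows, j1].astype(int)
            g2 = matrix.genotypes[rows, j2].astype(int)
            if len(set(g1)) == 1 or len(set(g2)) == 1:
                continue
            val = r2_em(g1, g2)
            if np.isfinite(val):
                between.append(val)
        assert within.size > 50
        assert within.mean() > 2 * np.mean(between)

    def test_composite_estimator_available(self, colony_data):
        res = pairwise_r2(
            colony_data["sparse"], colony_data["catalog"], "Tern",
            k_subsample=8, seed=4, method="composite",
        )
        assert all(0.0 <= r <= 1.0 + 1e-9 for *_, r in res.records)


class TestSmoothDecay:
    def test_constant_input_flat_fit(self):
        pairs = np.column_stack([np.arange(1, 41), np.full(40, 0.37)])
        sm = smooth_decay(pairs, span=0.5)
        assert np.allclose(sm[:, 1], 0.37, atol=1e-9)

    def test_monotone_noiseless_input_monotone_fit(self):
        x = np.arange(1, 61, dtype=float)
        pairs = np.column_stack([x, 1.0 / (1.0 + 0.1 * x)])
        sm = smooth_decay(pairs, span=0.4)
        assert np.all(np.diff(sm[:, 1]) <= 1e-9)

    def test_fit_within_local_window_range(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 89, 80)
        y = rng.uniform(0, 1, 80)
        pairs = np.column_stack([x, y])
        span = 0.6
        sm = smooth_decay(pairs, span=span)
        k = int(np.ceil(span * x.size))
        for x0, fit, _ in sm:
            d = np.abs(x - x0)
            window = y[np.argsort(d)[:k]]
            # local linear fits can overshoot slightly at the boundary
            margin = 0.25 * (window.max() - window.min())
            assert window.min() - margin <= fit <= window.max() + margin

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            smooth_decay(np.array([[1.0, 0.5]] * 5))
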