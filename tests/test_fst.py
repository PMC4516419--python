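import numpy as np
import pytest

from radpop.fst import (
    _wc_components,
    assignment_test,
    dapc_lite,
    fst_permutation_test,
    wc_fst,
)
from radpop.matrix import MISSING
from radpop.simulate import MigrationModel, simulate_dataset

from conftest import make_matrix
from oracles import expected_wc_fst, wc_components_bruteforce


def two_pop_matrix(genotypes, n_a):
    g = np.asarray(genotypes, dtype=np.int8)
    pops = ["A"] * n_a + ["B"] * (g.shape[0] - n_a)
    return make_matrix(g, populations=pops)


class TestWcFst:
    def test_fixed_difference_gives_one(self):
        g = [[0, 0], [0, 0], [2, 2], [2, 2]]
        res = wc_fst(two_pop_matrix(g, 2), "A", "B")
        assert res.fst_global == pytest.approx(1.0)

    def test_agrees_with_bruteforce_components(self):
        """Ratio-of-sums estimate matches independently tallied a, b, c
        on random small instances to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_a, n_b = rng.integers(3, 9, size=2)
            n_snps = int(rng.integers(2, 8))
            g = rng.integers(0, 3, size=(n_a + n_b, n_snps)).astype(np.int8)
            m = two_pop_matrix(g, int(n_a))
            res = wc_fst(m, "A", "B")
            num = den = 0.0
            for j in range(n_snps):
                ga = [int(x) for x in g[:n_a, j]]
                gb = [int(x) for x in g[n_a:, j]]
                pa = sum(ga) / (2 * len(ga))
                pb = sum(gb) / (2 * len(gb))
                pooled = (sum(ga) + sum(gb)) / (2 * (len(ga) + len(gb)))
                if pooled in (0.0, 1.0):
                    continue
                a, b, c = wc_components_bruteforce([ga, gb])
                num += a
                den += a + b + c
            assert res.fst_global == pytest.approx(num / den, abs=1e-12)

    def test_panmictic_near_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, size=1000)
        g = rng.binomial(2, p, size=(100, 1000)).astype(np.int8)
        res = wc_fst(two_pop_matrix(g, 50), "A", "B")
        assert abs(res.fst_global) < 0.01

    def test_island_model_matches_coalescent_expectation(self, island_data):
        """Mean W-C FST over 2,500 loci within 20% of the exact two-lineage
        coalescence-time expectation (Tb - Tw)/Tb of the simulated model."""
        m = island_data["matrix"]
        theta, M = island_data["theta"], island_data["M"]
        Mmat = np.array([[0.0, M], [M, 0.0]])
        expected = expected_wc_fst([theta, theta], Mmat, (0, 1))
        res = wc_fst(m, "a", "b")
        assert res.fst_global == pytest.approx(expected, rel=0.20)

    def test_invariant_to_snp_order_and_relabel(self, island_data):
        m = island_data["matrix"]
        base = wc_fst(m, "a", "b").fst_global
        rng = np.random.default_rng(3)
        perm = rng.permutation(m.n_snps)
        shuffled = m.subset_snps(perm)
        assert wc_fst(shuffled, "a", "b").fst_global == pytest.approx(base, abs=1e-12)
        flipped = m.relabel_alleles(range(0, m.n_snps, 2))
        assert wc_fst(flipped, "a", "b").fst_global == pytest.approx(base, abs=1e-12)

    def test_absent_population_rejected(self, island_data):
        with pytest.raises(KeyError):
            wc_fst(island_data["matrix"], "a", "zzz")


class TestPermutationTest:
    def test_extreme_observed_gives_min_p(self):
        g = np.array([[0, 0]] * 6 + [[2, 2]] * 6, dtype=np.int8)
        res = fst_permutation_test(two_pop_matrix(g, 6), "A", "B", n_perm=99, seed=1)
        assert res.p_value == pytest.approx(0.01)

    def test_null_mean_near_zero(self, island_data):
        """The pair-pooled exchangeability null is centred at zero even when
        the two populations are strongly differentiated."""
        res = fst_permutation_test(
            island_data["matrix"], "a", "b", n_perm=99, seed=5, pool="pair"
        )
        null = res.null_distribution
        assert abs(null.mean()) < 2 * null.std() / np.sqrt(null.size)

    def test_all_pool_null_broader_than_pair_pool(self, colony_data):
        """Permuting all individuals folds the Japan-Hawaii divergence into
        the within-Hawaii null, broadening it relative to the pair pool."""
        m = colony_data["sparse"]
        res_all = fst_permutation_test(m, "Tern", "Midway", n_perm=49, seed=8, pool="all")
        res_pair = fst_permutation_test(m, "Tern", "Midway", n_perm=49, seed=8, pool="pair")
        assert res_all.null_distribution.std() > res_pair.null_distribution.std()

    def test_panmictic_p_roughly_uniform(self):
        """Under label exchangeability p is uniform on its support."""
        rng = np.random.default_rng(17)
        ps = []
        for rep in range(40):
            p = rng.uniform(0.2, 0.8, size=60)
            g = rng.binomial(2, p, size=(20, 60)).astype(np.int8)
            res = fst_permutation_test(two_pop_matrix(g, 10), "A", "B", n_perm=19, seed=rep)
            ps.append(res.p_value)
        ps = np.array(ps)
        # mean of U{0.05,...,1.0} is 0.525, sd ~0.29
        assert abs(ps.mean() - 0.525) < 3 * 0.29 / np.sqrt(ps.size)
        assert ps.min() < 0.3 and ps.max() > 0.7


class TestDapc:
    def test_separated_clusters_on_first_axis(self):
        rng = np.random.default_rng(2)
        g = np.vstack(
            [
                rng.binomial(2, 0.05, size=(10, 80)),
                rng.binomial(2, 0.95, size=(10, 80)),
            ]
        ).astype(np.int8)
        m = two_pop_matrix(g, 10)
        res = dapc_lite(m, n_pcs=3, n_axes=1)
        c = res.coordinates[:, 0]
        between = abs(c[:10].mean() - c[10:].mean())
        within = max(c[:10].std(), c[10:].std())
        assert between > 5 * within

    def test_single_group_rejected(self):
        g = np.random.default_rng(0).integers(0, 3, size=(6, 10)).astype(np.int8)
        m = make_matrix(g)
        with pytest.raises(ValueError):
            dapc_lite(m, n_pcs=2, n_axes=1)

    def test_axes_bounded_by_groups(self, colony_data):
        with pytest.raises(ValueError):
            dapc_lite(colony_data["sparse"], n_pcs=3, n_axes=3)

    def test_eigenvalues_non_increasing(self, colony_data):
        res = dapc_lite(colony_data["sparse"], n_pcs=3, n_axes=2)
        assert res.eigenvalues[0] >= res.eigenvalues[1] >= 0


class TestAssignment:
    def test_private_allele_drives_assignment(self):
        g = np.zeros((8, 6), dtype=np.int8)
        g[4:, :] = 2  # pop B fixed for alternate
        m = two_pop_matrix(g, 4)
        res = assignment_test(m)
        assert res.assigned == ["A"] * 4 + ["B"] * 4

    def test_panmictic_accuracy_near_chance(self):
        rng = np.random.default_rng(31)
        accs = []
        for rep in range(10):
            p = rng.uniform(0.2, 0.8, size=100)
            g = rng.binomial(2, p, size=(30, 100)).astype(np.int8)
            m = two_pop_matrix(g, 15)
            res = assignment_test(m, seed=rep)
            acc = np.mean(np.array(res.assigned) == np.array(res.populations))
            accs.append(acc)
        # chance level 1/2; leave-one-out avoids self-assignment bias
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_replicates_recorded(self, colony_data):
        res = assignment_test(colony_data["sparse"], n_replicates=3, seed=9)
        assert len(res.replicate_assignments) == 3
        assert all(len(r) == 47 for r in res.replicate_assignments)
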