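import numpy as np
import pytest

from radpop.matrix import MISSING
from radpop.simulate import (
    LocusSimulationError,
    MigrationModel,
    MorphModel,
    apply_dropout,
    assemble_genotypes,
    default_morph_model,
    drop_mutations,
    simulate_dataset,
    simulate_genealogy,
    simulate_morphology,
    three_colony_model,
)

THETA = 0.054  # 0.0006/site x 90 bp


def one_deme(n_diploids, theta=THETA):
    return MigrationModel(["a"], [theta], np.zeros((1, 1)), [n_diploids], n_loci=1)


def test_two_lineage_coalescence_time_mean():
    """E[T2] = theta/2 in mutation-scaled units (10^4 replicates, 3 SE)."""
    rng = np.random.default_rng(101)
    model = one_deme(1)
    heights = np.array([simulate_genealogy(model, rng).time.max() for _ in range(10_000)])
    se = heights.std() / 100
    assert abs(heights.mean() - THETA / 2) < 3 * se


def test_disconnected_deme_warns_and_aborts():
    model = MigrationModel(
        ["a", "b"], [THETA, THETA], np.zeros((2, 2)), [1, 1], n_loci=1
    )
    rng = np.random.default_rng(0)
    with pytest.warns(UserWarning, match="disconnected"):
        with pytest.raises(LocusSimulationError):
            simulate_genealogy(model, rng)


def test_leaf_count_matches_study_sample_sizes():
    rng = np.random.default_rng(3)
    tree = simulate_genealogy(three_colony_model(), rng)
    assert tree.n_leaves == 2 * (17 + 11 + 19) == 94


def test_segregating_sites_match_watterson_expectation():
    """E[S] = theta * a1 for n haploid lineages (Monte Carlo, 3 SE)."""
    rng = np.random.default_rng(7)
    model = one_deme(5)  # 10 haploids
    a1 = sum(1.0 / i for i in range(1, 10))
    counts = []
    for _ in range(5000):
        tree = simulate_genealogy(model, rng)
        pos, _ = drop_mutations(tree, 90, rng)
        counts.append(pos.size)
    counts = np.array(counts)
    se = counts.std() / np.sqrt(counts.size)
    assert abs(counts.mean() - THETA * a1) < 3 * se


def test_segregating_sites_agree_with_msprime():
    """Cross-check mean S against an independent coalescent simulator."""
    msprime = pytest.importorskip("msprime")
    n_dip, reps = 10, 3000
    rng = np.random.default_rng(11)
    model = one_deme(n_dip)
    ours = []
    for _ in range(reps):
        tree = simulate_genealogy(model, rng)
        pos, _ = drop_mutations(tree, 90, rng)
        ours.append(pos.size)
    ours = np.array(ours)
    # msprime: theta = 4*Ne*mu_locus; choose Ne = 1/4, mutation rate theta
    theirs = []
    reps_ts = msprime.sim_ancestry(
        samples=n_dip, ploidy=2, population_size=0.25,
        num_replicates=reps, random_seed=17,
    )
    seed_rng = np.random.default_rng(19)
    for ts in reps_ts:
        mts = msprime.sim_mutations(
            ts, rate=THETA, random_seed=int(seed_rng.integers(1, 2**31)),
            discrete_genome=False,
        )
        theirs.append(mts.num_sites)
    theirs = np.array(theirs)
    se = np.sqrt(ours.var() / reps + theirs.var() / reps)
    assert abs(ours.mean() - theirs.mean()) < 3 * se


def test_single_deme_sfs_matches_neutral_expectation():
    """Folded site counts follow the theta/i frequency spectrum (chi^2 GOF)."""
    from scipy.stats import chisquare

    rng = np.random.default_rng(23)
    model = one_deme(5)  # n = 10 haploids
    n = 10
    counts = np.zeros(n - 1)
    for _ in range(4000):
        tree = simulate_genealogy(model, rng)
        _, haps = drop_mutations(tree, 90, rng)
        for col in haps.T:
            counts[col.sum() - 1] += 1
    expected = 1.0 / np.arange(1, n)
    expected = expected / expected.sum() * counts.sum()
    stat, p = chisquare(counts, expected)
    assert p > 0.01


def test_zero_length_branches_carry_no_mutations():
    from radpop.simulate import Genealogy

    tree = Genealogy(
        parent=np.array([2, 2, -1]),
        time=np.array([0.0, 0.0, 0.0]),
        n_leaves=2,
        leaf_deme=np.zeros(2, dtype=int),
    )
    rng = np.random.default_rng(0)
    pos, haps = drop_mutations(tree, 90, rng)
    assert pos.size == 0 and haps.shape == (2, 0)


def test_polymorphic_locus_fraction_magnitude():
    """At theta ~ 0.054/locus and ~90 lineages, roughly a quarter to a third
    of loci segregate (matches the observed RAD polymorphism rate)."""
    matrix, catalog = simulate_dataset(three_colony_model(n_loci=400, seed=9))
    poly = len({l for l, _ in matrix.snp_ids})
    frac = poly / len(catalog)
    assert 0.15 < frac < 0.45


class TestAssembleGenotypes:
    def _haps(self, arr):
        return {"L0": np.asarray(arr, dtype=np.int8)}

    def test_zero_dropout_complete(self):
        haps = self._haps([[0, 1], [1, 1], [0, 0], [1, 0]])
        m = assemble_genotypes(
            haps, [("L0", 3), ("L0", 8)], np.zeros(4, dtype=int), ["a"], 0.0, 1
        )
        assert m.completeness() == 1.0
        assert m.n_individuals == 2

    def test_identical_haplotypes_never_heterozygous(self):
        haps = self._haps([[1, 0, 1], [1, 0, 1]])
        m = assemble_genotypes(
            haps, [("L0", 0), ("L0", 1), ("L0", 2)], np.zeros(2, dtype=int), ["a"], 0.0, 1
        )
        assert set(np.unique(m.genotypes)) <= {0, 2}

    def test_odd_haplotype_count_rejected(self):
        haps = self._haps([[0], [1], [0]])
        with pytest.raises(ValueError, match="odd"):
            assemble_genotypes(haps, [("L0", 0)], np.zeros(3, dtype=int), ["a"], 0.0, 1)

    def test_dropout_rate_reflected_in_completeness(self, colony_data):
        sparse = colony_data["sparse"]
        n_cells = sparse.genotypes.size
        se = np.sqrt(0.196 * 0.804 / n_cells)
        assert abs((1 - sparse.completeness()) - 0.196) < 4 * se


def test_dataset_reproducible_from_seed():
    m1, c1 = simulate_dataset(three_colony_model(n_loci=60, seed=5))
    m2, c2 = simulate_dataset(three_colony_model(n_loci=60, seed=5))
    np.testing.assert_array_equal(m1.genotypes, m2.genotypes)
    assert m1.snp_ids == m2.snp_ids and c1.loci == c2.loci
    m3 = apply_dropout(m1, 0.2, 9)
    m4 = apply_dropout(m2, 0.2, 9)
    np.testing.assert_array_equal(m3.genotypes, m4.genotypes)


class TestMorphology:
    def test_sd_zero_limit_returns_cell_means(self):
        model = default_morph_model(seed=4)
        for t in model.sds:
            model.sds[t] = 1e-12
        table = simulate_morphology(model)
        japan_m = table[(table.population == "Japan") & (table.sex == "M")]
        assert japan_m["tarsus"].dropna().values == pytest.approx(
            model.means[("Japan", "M")]["tarsus"], abs=1e-6
        )

    def test_per_trait_usable_rows_match_preparation_losses(self):
        table = simulate_morphology(default_morph_model(seed=8))
        counts = {t: int(table[t].notna().sum()) for t in
                  ("wing_chord", "tarsus", "culmen", "bill_width")}
        assert counts == {"wing_chord": 33, "tarsus": 34, "culmen": 34, "bill_width": 32}

    def test_cell_means_recovered_at_large_n(self):
        model = default_morph_model(seed=15)
        big = {k: {t: 10_000 for t in model.traits} for k in model.cell_sizes}
        model = MorphModel(model.traits, model.means, model.sds, big, seed=15)
        table = simulate_morphology(model)
        cell = table[(table.population == "Hawaii") & (table.sex == "F")]
        for trait in model.traits:
            mean = cell[trait].mean()
            se = model.sds[trait] / 100
            assert abs(mean - model.means[("Hawaii", "F")][trait]) < 3 * se
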