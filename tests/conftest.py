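import numpy as np
import pytest

from radpop.matrix import GenotypeMatrix, LocusCatalog
from radpop.simulate import apply_dropout, simulate_dataset, three_colony_model


def make_matrix(genotypes, populations=None, individuals=None, snp_ids=None):
    """Small-matrix builder for hand-written examples."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    if populations is None:
        populations = ["pop1"] * n
    if individuals is None:
        individuals = [f"ind{i}" for i in range(n)]
    if snp_ids is None:
        snp_ids = [(f"L{j}", 0) for j in range(m)]
    return GenotypeMatrix(individuals, populations, g, snp_ids)


@pytest.fixture(scope="session")
def colony_data():
    """Study-scale three-colony simulation shared across the suite.

    2,500 loci at theta = 0.0006/site with 19.6% genotype dropout: the
    weak-differentiation, low-diversity regime at the study's sample sizes
    (17/11/19 diploids).
    """
    matrix, catalog = simulate_dataset(three_colony_model(n_loci=2500, seed=20240))
    sparse = apply_dropout(matrix, 0.196, seed=77)
    return {"complete": matrix, "sparse": sparse, "catalog": catalog}


@pytest.fixture(scope="session")
def single_deme_5000():
    """Single population, 5,000 loci at theta = 0.0006/site (20 diploids)."""
    from radpop.simulate import MigrationModel

    model = MigrationModel(
        ["a"], [0.054], np.zeros((1, 1)), [20], n_loci=5000, seed=606
    )
    return simulate_dataset(model)


@pytest.fixture(scope="session")
def island_data():
    """Symmetric 2-deme island model with theta*M = 1 (2,500 loci)."""
    from radpop.simulate import MigrationModel

    theta = 0.054
    M = 1.0 / theta
    model = MigrationModel(
        demes=["a", "b"],
        theta=[theta, theta],
        M=np.array([[0.0, M], [M, 0.0]]),
        samples_per_deme=[8, 8],
        n_loci=2500,
        seed=424242,
    )
    matrix, catalog = simulate_dataset(model)
    return {"matrix": matrix, "catalog": catalog, "theta": theta, "M": M}
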