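"""Structured-coalescent simulation of RAD-like SNP data, plus morphometrics.

The genealogical model is the n-deme structured coalescent with migration,
parameterised the way coalescent gene-flow software reports it: per-deme
Theta_i = 4*N_i*mu per locus, and a migration matrix M of mutation-scaled
rates m/mu, with row = receiving deme.  Time is measured in mutational
units (one unit = 1/mu generations at the per-locus mutation rate), so

* two lineages in deme i coalesce at rate 2/theta_i (k lineages: k(k-1)/theta_i),
* a lineage currently in deme i traces back to source deme j at rate M[i][j]
  (the mutation-scaled immigration rate into i from j),
* mutations fall on a branch as Poisson(branch length).

Under this scaling E[T2] = theta/2 for two lineages in one deme and the
expected number of segregating sites for n lineages is theta * sum_{i<n} 1/i,
which the test suite checks against closed forms and against an independent
coalescent simulator.

Mutations follow the infinite-sites model inside a fixed-length locus
(default 90 bp); two mutations landing on the same position are re-drawn,
a negligible correction at the low diversity simulated here
(theta per site ~ 6e-4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, GenotypeMatrix, LocusCatalog


class LocusSimulationError(RuntimeError):
    """A locus genealogy cannot complete (disconnected migration graph)."""


@dataclass
class MigrationModel:
    """Demographic model for the simulator.

    Parameters
    ----------
    demes : list of str
        Deme labels.
    theta : list of float
        Per-deme Theta = 4*N*mu per locus (locus-length scaled).
    M : array-like, shape (d, d)
        Mutation-scaled migration rates m/mu; ``M[i][j]`` is the rate into
        receiving deme i from source deme j.  Diagonal unused.
    samples_per_deme : list of int
        Diploid sample sizes.
    locus_length : int
        Locus length in bp.
    n_loci : int
        Number of independent loci to simulate.
    seed : int
        Seed for all randomness in the model.
    """

    demes: list[str]
    theta: list[float]
    M: np.ndarray
    samples_per_deme: list[int]
    locus_length: int = 90
    n_loci: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        d = len(self.demes)
        if len(self.theta) != d or len(self.samples_per_deme) != d:
            raise ValueError("theta and samples_per_deme must match demes")
        if self.M.shape != (d, d):
            raise ValueError(f"M must be {d}x{d}")
        if any(t <= 0 for t in self.theta):
            raise ValueError("theta must be positive for every deme")
        off = self.M[~np.eye(d, dtype=bool)]
        if (off < 0).any():
            raise ValueError("off-diagonal migration rates must be >= 0")
        if any(s < 1 for s in self.samples_per_deme):
            raise ValueError("at least one diploid sample per deme")


@dataclass
class Genealogy:
    """Binary coalescent tree over haploid lineages.

    ``parent[v]`` is -1 for the root; ``time[v]`` is the node age in
    mutational units; leaves are nodes ``0 .. n_leaves-1`` and
    ``leaf_deme[v]`` gives their deme index.
    """

    parent: np.ndarray
    time: np.ndarray
    n_leaves: int
    leaf_deme: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        lengths = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        lengths[has_parent] = (
            self.time[self.parent[has_parent]] - self.time[has_parent]
        )
        return lengths

    def leaves_below(self) -> list[np.ndarray]:
        """Leaf sets under each node, computed bottom-up."""
        below: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for v in range(self.n_leaves):
            below[v].add(v)
        # nodes are created in increasing time order, so a single pass works
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                below[p].update(below[v])
        return [np.fromiter(sorted(s), dtype=int) for s in below]


def _check_connected(model: MigrationModel) -> None:
    d = len(model.demes)
    if d == 1:
        return
    adj = (model.M > 0) & ~np.eye(d, dtype=bool)
    # lineages can move along M[i][j] (i -> j backwards); require that all
    # sampled demes fall in one communicating class of the symmetrised graph
    reach = adj | adj.T
    seen = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(reach[i]):
            if j not in seen:
                seen.add(j)
                stack.append(j)
    if len(seen) != d:
        isolated = [model.demes[i] for i in range(d) if i not in seen]
        warnings.warn(
            f"demes {isolated} are disconnected from the migration graph; "
            "lineages sampled there can never coalesce with the rest",
            stacklevel=3,
        )
        raise LocusSimulationError(
            "zero migration between sampled demes: genealogy cannot complete"
        )


def simulate_genealogy(model: MigrationModel, rng: np.random.Generator) -> Genealogy:
    """Draw one locus genealogy under the structured coalescent.

    Events are competing exponentials: within-deme coalescence at rate
    k_i(k_i-1)/theta_i and per-lineage migration i -> j at rate M[i][j].
    """
    _check_connected(model)
    d = len(model.demes)
    n_leaves = 2 * int(np.sum(model.samples_per_deme))
    n_nodes = 2 * n_leaves - 1
    parent = np.full(n_nodes, -1, dtype=int)
    time = np.zeros(n_nodes)
    leaf_deme = np.repeat(np.arange(d), 2 * np.asarray(model.samples_per_deme))

    # active lineage lists per deme; event loop uses Python scalars, which is
    # far faster than numpy for the tiny (d <= handful) per-event arithmetic
    active: list[list[int]] = [[] for _ in range(d)]
    for v, deme in enumerate(leaf_deme):
        active[deme].append(v)
    theta = [float(x) for x in model.theta]
    Mrow = [[float(model.M[i, j]) if j != i else 0.0 for j in range(d)] for i in range(d)]
    mig_out = [sum(row) for row in Mrow]

    t = 0.0
    next_node = n_leaves
    n_active = n_leaves
    coal = [0.0] * d
    mig = [0.0] * d
    while n_active > 1:
        total = 0.0
        for i in range(d):
            k = len(active[i])
            coal[i] = k * (k - 1) / theta[i]
            mig[i] = k * mig_out[i]
            total += coal[i] + mig[i]
        t += rng.exponential(1.0 / total)
        u = rng.uniform(0.0, total)
        event_deme = -1
        for i in range(d):
            if u < coal[i]:
                event_deme = i
                break
            u -= coal[i]
        if event_deme >= 0:
            # coalescence in event_deme
            lineages = active[event_deme]
            k = len(lineages)
            a = int(rng.integers(k))
            b = int(rng.integers(k - 1))
            if b >= a:
                b += 1
            if a < b:
                a, b = b, a
            va = lineages.pop(a)
            vb = lineages.pop(b)
            parent[va] = parent[vb] = next_node
            time[next_node] = t
            lineages.append(next_node)
            next_node += 1
            n_active -= 1
        else:
            for i in range(d):
                if u < mig[i]:
                    break
                u -= mig[i]
            # choose source deme j with probability prop. to M[i][j]
            v_rate = rng.uniform(0.0, mig_out[i])
            j = 0
            for j in range(d):
                if v_rate < Mrow[i][j]:
                    break
                v_rate -= Mrow[i][j]
            idx = int(rng.integers(len(active[i])))
            v = active[i].pop(idx)
            active[j].append(v)
    return Genealogy(parent, time, n_leaves, leaf_deme)


def drop_mutations(
    tree: Genealogy, locus_length: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Place infinite-sites mutations on a genealogy.

    Returns ``(positions, haplotypes)``: sorted 0-based site positions within
    the locus and a (n_leaves, n_sites) 0/1 matrix of derived alleles.
    """
    lengths = tree.branch_lengths()
    total = lengths.sum()
    n_mut = rng.poisson(total) if total > 0 else 0
    if n_mut == 0:
        return np.empty(0, dtype=int), np.empty((tree.n_leaves, 0), dtype=np.int8)
    if n_mut > locus_length:
        # infinite-sites cannot host more mutations than sites; at the low
        # theta used here this is effectively unreachable
        n_mut = locus_length
    branches = rng.choice(tree.n_nodes, size=n_mut, p=lengths / total)
    positions: list[int] = []
    used: set[int] = set()
    for _ in range(n_mut):
        pos = int(rng.integers(locus_length))
        while pos in used:  # collision: re-draw
            pos = int(rng.integers(locus_length))
        used.add(pos)
        positions.append(pos)
    order = np.argsort(positions)
    below = tree.leaves_below()
    haplotypes = np.zeros((tree.n_leaves, n_mut), dtype=np.int8)
    for col, m in enumerate(order):
        haplotypes[below[branches[m]], col] = 1
    return np.asarray(positions)[order], haplotypes


def assemble_genotypes(
    haplotypes: dict[str, np.ndarray],
    snp_ids: list[tuple[str, int]],
    deme_of_hap: np.ndarray,
    demes: list[str],
    dropout_rate: float,
    seed: int,
) -> GenotypeMatrix:
    """Pair haplotypes into diploids within demes and apply missingness.

    ``haplotypes`` maps locus ID to an (n_haplotypes, n_sites) 0/1 matrix;
    ``snp_ids`` lists the (locus, offset) columns in output order;
    per-cell missingness is Bernoulli(dropout_rate).
    """
    rng = np.random.default_rng(seed)
    n_hap = deme_of_hap.size
    if n_hap % 2:
        raise ValueError("odd total haplotype count cannot be paired")
    pair_a: list[int] = []
    pair_b: list[int] = []
    populations: list[str] = []
    individuals: list[str] = []
    for di, deme in enumerate(demes):
        idx = np.flatnonzero(deme_of_hap == di)
        if idx.size % 2:
            raise ValueError(f"deme {deme}: odd haplotype count {idx.size}")
        perm = rng.permutation(idx)
        for k in range(idx.size // 2):
            pair_a.append(int(perm[2 * k]))
            pair_b.append(int(perm[2 * k + 1]))
            populations.append(deme)
            individuals.append(f"{deme}_{k:02d}")
    hap_all = np.hstack([haplotypes[l] for l in dict.fromkeys(l for l, _ in snp_ids)])
    geno = (hap_all[pair_a] + hap_all[pair_b]).astype(np.int8)
    if dropout_rate > 0:
        mask = rng.random(geno.shape) < dropout_rate
        geno[mask] = MISSING
    return GenotypeMatrix(individuals, populations, geno, snp_ids)


def simulate_dataset(
    model: MigrationModel,
) -> tuple[GenotypeMatrix, LocusCatalog]:
    """Simulate a full RAD-like data set: genotype matrix + locus catalog.

    Every simulated locus appears in the catalog (monomorphic loci with no
    offsets); the genotype matrix holds only segregating sites.  Missingness
    is applied by :func:`apply_dropout` separately so the complete matrix is
    also available.
    """
    rng = np.random.default_rng(model.seed)
    d = len(model.demes)
    deme_of_hap = np.repeat(np.arange(d), 2 * np.asarray(model.samples_per_deme))
    haplotypes: dict[str, np.ndarray] = {}
    snp_ids: list[tuple[str, int]] = []
    loci: dict[str, tuple[int, tuple[int, ...]]] = {}
    n_hap = deme_of_hap.size
    for locus_index in range(model.n_loci):
        locus_id = f"L{locus_index:06d}"
        tree = simulate_genealogy(model, rng)
        positions, haps = drop_mutations(tree, model.locus_length, rng)
        loci[locus_id] = (model.locus_length, tuple(int(p) for p in positions))
        if positions.size:
            haplotypes[locus_id] = haps
            snp_ids.extend((locus_id, int(p)) for p in positions)
    if not snp_ids:
        raise RuntimeError("no segregating sites simulated; increase n_loci/theta")
    matrix = assemble_genotypes(
        haplotypes,
        snp_ids,
        deme_of_hap,
        model.demes,
        dropout_rate=0.0,
        seed=int(np.random.default_rng(model.seed + 1).integers(2**31)),
    )
    return matrix, LocusCatalog(loci)


def apply_dropout(
    matrix: GenotypeMatrix, dropout_rate: float, seed: int
) -> GenotypeMatrix:
    """Mask each genotype cell independently with probability ``dropout_rate``."""
    rng = np.random.default_rng(seed)
    geno = matrix.genotypes.copy()
    geno[rng.random(geno.shape) < dropout_rate] = MISSING
    return GenotypeMatrix(matrix.individuals, matrix.populations, geno, matrix.snp_ids)


def expected_pair_times(theta: list[float], M: np.ndarray) -> dict:
    """Exact E[coalescence time] for two lineages, per deme-pair placement.

    Solves the absorbing Markov chain of the two-lineage structured
    coalescent (states are unordered deme pairs).  Within-deme entries give
    expected nucleotide diversity (pi = 2 * E[T] per locus in these units);
    (Tb - Tw)/Tb gives the low-mutation expectation of pairwise FST.
    """
    d = len(theta)
    states = [(i, j) for i in range(d) for j in range(i, d)]
    index = {s: k for k, s in enumerate(states)}
    A = np.eye(len(states))
    b = np.zeros(len(states))
    for k, (i, j) in enumerate(states):
        coal = 2.0 / theta[i] if i == j else 0.0
        moves = []
        for src, other in ((i, j), (j, i)):
            for dst in range(d):
                if dst != src and M[src][dst] > 0:
                    moves.append((M[src][dst], tuple(sorted((dst, other)))))
        total = coal + sum(r for r, _ in moves)
        b[k] = 1.0 / total
        for rate, ns in moves:
            A[k, index[ns]] -= rate / total
    ET = np.linalg.solve(A, b)
    return {s: float(ET[k]) for k, s in enumerate(states)}


def three_colony_model(
    n_loci: int = 3000,
    seed: int = 0,
    theta_per_site: float = 0.0006,
    locus_length: int = 90,
) -> MigrationModel:
    """Default model emulating three albatross breeding colonies.

    Two Hawaiian demes (Tern, 17 diploids; Midway, 11) exchange migrants at
    a much higher mutation-scaled rate than either does with the Japanese
    deme (Torishima, 19), with near-symmetric migration.  Two calibrations
    against the exact two-lineage coalescence times of the model:

    * migration-rate ratios are set so expected pairwise Weir-Cockerham FST
      is ~0.045 between Japan and either Hawaiian deme (weak but
      detectable) and ~0.006 within Hawaii (below the permutation-null
      resolution at these sample sizes: the Hawaiian colonies behave as one
      nearly panmictic population);
    * theta and M are then jointly rescaled (theta -> c*theta, M -> M/c,
      which rescales all coalescence times by c and leaves every FST
      invariant) so that the expected within-deme nucleotide diversity per
      site equals ``theta_per_site``.  With multiple connected demes the
      species-wide genealogy is deeper than a single deme's, so the
      per-deme coalescent parameter is smaller than the observed
      within-population diversity.
    """
    base_theta = 0.054
    m_within_hawaii = 1500.0
    m_japan = 100.0
    M = np.array(
        [
            [0.0, m_within_hawaii, m_japan],
            [m_within_hawaii, 0.0, m_japan],
            [m_japan, m_japan, 0.0],
        ]
    )
    ET = expected_pair_times([base_theta] * 3, M)
    pi_locus_model = 2.0 * np.mean([ET[(i, i)] for i in range(3)])
    c = theta_per_site * locus_length / pi_locus_model
    return MigrationModel(
        demes=["Tern", "Midway", "Torishima"],
        theta=[base_theta * c] * 3,
        M=M / c,
        samples_per_deme=[17, 11, 19],
        locus_length=locus_length,
        n_loci=n_loci,
        seed=seed,
    )


# -- morphometrics -----------------------------------------------------------


@dataclass
class MorphModel:
    """Per (population x sex) cell normal model for morphometric traits.

    ``means[(pop, sex)][trait]`` and ``sds[trait]`` are in mm;
    ``cell_sizes[(pop, sex)][trait]`` gives per-trait usable sample sizes
    (traits unavailable on some museum preparations give unequal n).
    """

    traits: list[str]
    means: dict[tuple[str, str], dict[str, float]]
    sds: dict[str, float]
    cell_sizes: dict[tuple[str, str], dict[str, int]]
    seed: int = 0

    def __post_init__(self) -> None:
        if any(sd <= 0 for sd in self.sds.values()):
            raise ValueError("trait SDs must be positive")


#: Traits measured on museum skins, mm.
MORPH_TRAITS = ["wing_chord", "tarsus", "culmen", "bill_width"]

# Grand means (mm), Hawaii-minus-Japan location differences and male-minus-
# female sex differences used by the default two-population morph model.
_GRAND_MEAN = {"wing_chord": 494.2, "tarsus": 98.5, "culmen": 103.3, "bill_width": 30.2}
_LOC_DIFF = {"wing_chord": 9.1, "tarsus": -11.9, "culmen": 3.2, "bill_width": -0.8}
_SEX_DIFF = {"wing_chord": 0.0, "tarsus": 0.0, "culmen": 3.2, "bill_width": 1.3}
_SD = {"wing_chord": 19.5, "tarsus": 8.5, "culmen": 3.0, "bill_width": 1.3}
# per-trait usable specimens per cell, order wing/tarsus/culmen/width
_CELL_N = {
    ("Japan", "M"): dict(zip(MORPH_TRAITS, (8, 9, 9, 9))),
    ("Japan", "F"): dict(zip(MORPH_TRAITS, (7, 7, 8, 8))),
    ("Hawaii", "M"): dict(zip(MORPH_TRAITS, (9, 8, 9, 8))),
    ("Hawaii", "F"): dict(zip(MORPH_TRAITS, (9, 10, 8, 7))),
}


def default_morph_model(seed: int = 0) -> MorphModel:
    """Two-population, two-sex albatross morphometric model (mm)."""
    means: dict[tuple[str, str], dict[str, float]] = {}
    for pop in ("Hawaii", "Japan"):
        for sex in ("M", "F"):
            cell = {}
            for t in MORPH_TRAITS:
                loc = 0.5 if pop == "Hawaii" else -0.5
                sx = 0.5 if sex == "M" else -0.5
                cell[t] = _GRAND_MEAN[t] + loc * _LOC_DIFF[t] + sx * _SEX_DIFF[t]
            means[(pop, sex)] = cell
    return MorphModel(
        traits=list(MORPH_TRAITS),
        means=means,
        sds=dict(_SD),
        cell_sizes={k: dict(v) for k, v in _CELL_N.items()},
        seed=seed,
    )


def simulate_morphology(model: MorphModel):
    """Draw a specimen x trait table from the cell-means model.

    Returns a pandas DataFrame with columns specimen, population, sex and one
    column per trait; traits unavailable for a specimen are NaN, reproducing
    per-trait sample sizes.
    """
    import pandas as pd

    rng = np.random.default_rng(model.seed)
    records = []
    for (pop, sex), sizes in model.cell_sizes.items():
        n_cell = max(sizes.values())
        for i in range(n_cell):
            rec = {"specimen": f"{pop}_{sex}_{i:02d}", "population": pop, "sex": sex}
            records.append(rec)
        for trait in model.traits:
            n_t = sizes[trait]
            vals = model.means[(pop, sex)][trait] + model.sds[trait] * rng.standard_normal(
                n_cell
            )
            # drop the surplus specimens for this trait (preparation missing)
            keep = rng.choice(n_cell, size=n_t, replace=False)
            for i in range(n_cell):
                records[len(records) - n_cell + i][trait] = (
                    float(vals[i]) if i in keep else np.nan
                )
    return pd.DataFrame.from_records(records)
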