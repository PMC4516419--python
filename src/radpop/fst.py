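"""Population differentiation: Weir-Cockerham FST, permutation nulls,
PCA + discriminant ordination, and likelihood assignment tests.

The FST estimator is the Weir & Cockerham (1984) variance-component
theta-hat.  Per SNP the among-population (a), among-individual (b) and
within-individual (c) components are computed from allele frequencies and
observed heterozygote frequencies; the multi-SNP estimate is the
ratio of sums  sum(a) / sum(a + b + c).  Negative per-SNP values are kept
(they are part of the sampling distribution and of the permutation null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .matrix import MISSING, GenotypeMatrix


@dataclass
class FstResult:
    pair: tuple[str, str]
    fst_global: float
    fst_per_locus: np.ndarray
    snp_ids: list[tuple[str, int]]
    null_distribution: np.ndarray | None = None
    p_value: float | None = None


def _wc_components(
    genotypes: np.ndarray, groups: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Weir-Cockerham components (a, b, c) and a validity mask.

    ``groups`` lists row-index arrays, one per population.  SNPs where any
    population has fewer than two called genotypes, or where the pooled
    sample is monomorphic, are masked out.
    """
    r = len(groups)
    n = np.empty((r, genotypes.shape[1]))
    p = np.empty_like(n)
    h = np.empty_like(n)
    for i, rows in enumerate(groups):
        g = genotypes[rows]
        called = g != MISSING
        n[i] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[i] = np.where(called, g, 0).sum(axis=0) / (2.0 * n[i])
            h[i] = (g == 1).sum(axis=0) / n[i]
    valid = (n >= 2).all(axis=0)
    nbar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    valid &= np.isfinite(a + b + c)
    valid &= (pbar > 0) & (pbar < 1)
    return a, b, c, valid


def wc_fst(matrix: GenotypeMatrix, popA: str, popB: str) -> FstResult:
    """Pairwise Weir-Cockerham FST (global and per SNP), no null."""
    groups = [matrix.population_indices(popA), matrix.population_indices(popB)]
    a, b, c, valid = _wc_components(matrix.genotypes, groups)
    denom = a + b + c
    keep = valid & (denom != 0)
    if not keep.any():
        raise ValueError("no SNP with a defined Weir-Cockerham denominator")
    per_locus = a[keep] / denom[keep]
    fst_global = float(a[keep].sum() / denom[keep].sum())
    snp_ids = [matrix.snp_ids[j] for j in np.flatnonzero(keep)]
    return FstResult((popA, popB), fst_global, per_locus, snp_ids)


def fst_permutation_test(
    matrix: GenotypeMatrix,
    popA: str,
    popB: str,
    n_perm: int = 99,
    seed: int = 0,
    pool: str = "all",
) -> FstResult:
    """Permutation test of pairwise FST.

    Random groups of the two populations' sizes are drawn without
    replacement from the permutation pool and the global FST recomputed for
    each; p = (1 + #{null >= observed}) / (n_perm + 1), never zero.

    ``pool="all"`` (default) permutes every individual in the matrix, so
    with more than two populations the null absorbs any structure involving
    the unpermuted populations — the procedure used for the published
    pairwise tests, and deliberately conservative for weakly differentiated
    pairs.  ``pool="pair"`` permutes only the two populations compared (the
    classical exchangeability null, centred at zero).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if pool not in ("all", "pair"):
        raise ValueError(f"unknown permutation pool {pool!r}")
    rng = np.random.default_rng(seed)
    observed = wc_fst(matrix, popA, popB)
    rows_a = matrix.population_indices(popA)
    rows_b = matrix.population_indices(popB)
    if pool == "all":
        source = np.arange(matrix.n_individuals)
    else:
        source = np.concatenate([rows_a, rows_b])
    pool_rows = source
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(pool_rows)
        ga = perm[: rows_a.size]
        gb = perm[rows_a.size : rows_a.size + rows_b.size]
        a, b, c, valid = _wc_components(matrix.genotypes, [ga, gb])
        denom = a + b + c
        keep = valid & (denom != 0)
        null[k] = a[keep].sum() / denom[keep].sum()
    p = (1.0 + np.sum(null >= observed.fst_global)) / (n_perm + 1.0)
    return FstResult(
        (popA, popB),
        observed.fst_global,
        observed.fst_per_locus,
        observed.snp_ids,
        null_distribution=null,
        p_value=float(p),
    )


def fst_matrix(matrix: GenotypeMatrix, n_perm: int = 0, seed: int = 0) -> dict:
    """All pairwise FST values (optionally with permutation p-values)."""
    pops = matrix.population_set
    out = {}
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            if n_perm:
                res = fst_permutation_test(matrix, pops[i], pops[j], n_perm, seed + i * 31 + j)
            else:
                res = wc_fst(matrix, pops[i], pops[j])
            out[(pops[i], pops[j])] = res
    return out


# -- PCA + discriminant ordination ------------------------------------------


@dataclass
class DiscriminantResult:
    retained_pcs: int
    discriminant_axes: int
    coordinates: np.ndarray  # individuals x axes
    eigenvalues: np.ndarray  # non-increasing between/within ratios
    groups: list[str] = field(default_factory=list)


def dapc_lite(
    matrix: GenotypeMatrix,
    n_pcs: int = 3,
    n_axes: int = 2,
) -> DiscriminantResult:
    """PCA dimension reduction followed by a linear discriminant rotation.

    Missing genotypes are imputed to the per-SNP mean, columns are centred
    (no variance scaling, genotypes being 0/1/2 coded), the top ``n_pcs``
    principal components are retained, and discriminant axes maximising the
    between/within group variance ratio are extracted on the PC scores.
    Eigenvalues are the between/within ratios, non-increasing.
    """
    groups = matrix.population_set
    if len(groups) < 2:
        raise ValueError("discriminant analysis needs at least two groups")
    if n_axes >= len(groups) + 1 or n_axes > len(groups) - 1:
        raise ValueError(
            f"n_axes must be <= groups-1 ({len(groups) - 1}), got {n_axes}"
        )
    g = matrix.genotypes.astype(float)
    g[matrix.genotypes == MISSING] = np.nan
    col_mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(col_mean, inds[1])
    g -= col_mean
    # PCA via SVD
    u, s, _ = np.linalg.svd(g, full_matrices=False)
    k = min(n_pcs, int(np.sum(s > 1e-10)))
    scores = u[:, :k] * s[:k]
    # between/within scatter on PC scores
    labels = np.asarray(matrix.populations)
    grand = scores.mean(axis=0)
    Sw = np.zeros((k, k))
    Sb = np.zeros((k, k))
    for pop in groups:
        rows = labels == pop
        x = scores[rows]
        mu = x.mean(axis=0)
        d = x - mu
        Sw += d.T @ d
        dm = (mu - grand)[:, None]
        Sb += rows.sum() * (dm @ dm.T)
    Sw += 1e-10 * np.eye(k)  # guard perfect separation
    eigvals, eigvecs = sla.eigh(Sb, Sw)
    order = np.argsort(eigvals)[::-1][:n_axes]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    coords = scores @ eigvecs
    return DiscriminantResult(k, n_axes, coords, eigvals, groups)


# -- assignment tests --------------------------------------------------------


@dataclass
class AssignmentResult:
    individuals: list[str]
    populations: list[str]  # true labels
    log_likelihood: np.ndarray  # individuals x candidate populations
    assigned: list[str]
    candidate_populations: list[str]
    replicate_assignments: list[list[str]] = field(default_factory=list)


def _genotype_loglik(g_row: np.ndarray, p: np.ndarray, floor: float) -> float:
    """Hardy-Weinberg log-likelihood of one individual's genotypes."""
    called = g_row != MISSING
    g = g_row[called]
    q = np.clip(p[called], floor, 1.0 - floor)
    ll = np.empty(g.size)
    ll[g == 0] = 2.0 * np.log(1.0 - q[g == 0])
    ll[g == 1] = np.log(2.0) + np.log(q[g == 1]) + np.log(1.0 - q[g == 1])
    ll[g == 2] = 2.0 * np.log(q[g == 2])
    return float(ll.sum())


def assignment_test(
    matrix: GenotypeMatrix, n_replicates: int = 0, seed: int = 0
) -> AssignmentResult:
    """Assign individuals to populations by Hardy-Weinberg likelihood.

    Allele frequencies for an individual's own population are computed
    leave-one-out; zero/one frequencies are floored at 1/(2n+1).  Optional
    replicates bootstrap individuals within populations and re-run the
    assignment, mimicking resampled-data-set assignment procedures.
    """
    pops = matrix.population_set
    if len(pops) < 2:
        raise ValueError("assignment requires >=2 populations")
    rng = np.random.default_rng(seed)

    def run(m: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
        labels = np.asarray(m.populations)
        freqs = {}
        counts = {}
        for pop in pops:
            rows = m.population_indices(pop)
            alt, n_chrom = m.allele_counts(rows)
            freqs[pop] = (alt, n_chrom)
        ll = np.empty((m.n_individuals, len(pops)))
        for i in range(m.n_individuals):
            g_row = m.genotypes[i]
            called = g_row != MISSING
            for c, pop in enumerate(pops):
                alt, n_chrom = freqs[pop]
                alt_i, nc_i = alt.copy(), n_chrom.copy()
                if labels[i] == pop:  # leave-one-out
                    alt_i = alt_i - np.where(called, g_row, 0)
                    nc_i = nc_i - 2.0 * called
                with np.errstate(invalid="ignore", divide="ignore"):
                    p = np.where(nc_i > 0, alt_i / nc_i, 0.5)
                n_med = max(np.median(nc_i[nc_i > 0]) if (nc_i > 0).any() else 1, 1)
                floor = 1.0 / (n_med + 1.0)
                ll[i, c] = _genotype_loglik(g_row, p, floor)
        assigned = [pops[int(np.argmax(ll[i]))] for i in range(m.n_individuals)]
        return ll, assigned

    ll, assigned = run(matrix)
    replicate_assignments: list[list[str]] = []
    for _ in range(n_replicates):
        rows = []
        for pop in pops:
            idx = matrix.population_indices(pop)
            rows.extend(rng.choice(idx, size=idx.size, replace=True))
        boot = matrix.subset_individuals(rows)
        _, boot_assigned = run(boot)
        replicate_assignments.append(boot_assigned)
    return AssignmentResult(
        list(matrix.individuals),
        list(matrix.populations),
        ll,
        assigned,
        pops,
        replicate_assignments,
    )
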