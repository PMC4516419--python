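"""Independent oracles used by the test suite.

Everything here is written from first principles (Markov chains, explicit
tallies, grid search, textbook regression algebra) and deliberately does not
share code with the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# -- structured-coalescent expectations -------------------------------------


def pairwise_coalescence_times(theta: list[float], M: np.ndarray) -> dict:
    """E[coalescence time] for two lineages at every deme-pair configuration.

    Solves the absorbing Markov chain of the two-lineage structured
    coalescent exactly (states = unordered deme pairs; coalescence absorbs).
    Times are in the same mutation-scaled units as the simulator.
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
        for r, ns in moves:
            A[k, index[ns]] -= r / total
    ET = np.linalg.solve(A, b)
    return {s: float(ET[k]) for k, s in enumerate(states)}


def expected_wc_fst(theta: list[float], M: np.ndarray, pair: tuple[int, int]) -> float:
    """Low-mutation expectation of Weir-Cockerham FST between two sampled demes.

    The ratio-of-sums W-C estimator converges to (Tb - Tw) / Tb, where Tw is
    the mean within-deme and Tb the between-deme two-lineage coalescence
    time of the full model.
    """
    ET = pairwise_coalescence_times(theta, M)
    i, j = pair
    Tw = 0.5 * (ET[(i, i)] + ET[(j, j)])
    Tb = ET[tuple(sorted(pair))]
    return (Tb - Tw) / Tb


# -- Weir-Cockerham per-SNP components, independent coding ------------------


def wc_components_bruteforce(genotype_lists: list[list[int]]) -> tuple[float, float, float]:
    """(a, b, c) variance components for one SNP from per-population
    genotype lists (codes 0/1/2, no missing), tallied longhand."""
    r = len(genotype_lists)
    n = [len(g) for g in genotype_lists]
    p = [sum(g) / (2.0 * len(g)) for g in genotype_lists]
    h = [sum(1 for x in g if x == 1) / len(g) for g in genotype_lists]
    nbar = sum(n) / r
    nc = (sum(n) - sum(ni**2 for ni in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


# -- two-locus haplotype likelihood / grid oracle ---------------------------


def table_loglik(table: np.ndarray, h: np.ndarray) -> float:
    """Log-likelihood of a 3x3 genotype table under haplotype freqs
    (hAB, hAb, haB, hab), assuming random union of gametes."""
    hAB, hAb, haB, hab = h
    # genotype (g1, g2) probabilities; allele A/B = "2" allele at SNP 1/2
    probs = np.empty((3, 3))
    probs[2, 2] = hAB**2
    probs[2, 1] = 2 * hAB * hAb
    probs[2, 0] = hAb**2
    probs[1, 2] = 2 * hAB * haB
    probs[1, 1] = 2 * hAB * hab + 2 * hAb * haB
    probs[1, 0] = 2 * hAb * hab
    probs[0, 2] = haB**2
    probs[0, 1] = 2 * haB * hab
    probs[0, 0] = hab**2
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(table > 0, table * np.log(np.maximum(probs, 1e-300)), 0.0)
    return float(ll.sum())


def _grid_loglik(table: np.ndarray, pA: float, pB: float, D: np.ndarray) -> np.ndarray:
    """Vectorised log-likelihood of the table over a vector of D values."""
    hAB = pA * pB + D
    hAb = pA * (1 - pB) - D
    haB = (1 - pA) * pB - D
    hab = (1 - pA) * (1 - pB) + D
    probs = np.empty((3, 3, D.size))
    probs[2, 2] = hAB**2
    probs[2, 1] = 2 * hAB * hAb
    probs[2, 0] = hAb**2
    probs[1, 2] = 2 * hAB * haB
    probs[1, 1] = 2 * hAB * hab + 2 * hAb * haB
    probs[1, 0] = 2 * hAb * hab
    probs[0, 2] = haB**2
    probs[0, 1] = 2 * haB * hab
    probs[0, 0] = hab**2
    logp = np.log(np.maximum(probs, 1e-300))
    return np.einsum("ij,ijk->k", table.astype(float), logp)


def grid_mle_r2(table: np.ndarray, n_grid: int = 2001) -> float:
    """Exhaustive-grid ML r^2 for a 3x3 genotype table.

    Allele frequencies are fixed at their (margin-preserving) ML values and
    the gametic disequilibrium D is profiled over its admissible interval on
    a dense grid, followed by one local refinement pass.
    """
    n = table.sum()
    # genotype margins -> allele frequencies (these are the MLEs; any
    # haplotype solution reproduces them)
    g1 = table.sum(axis=1)
    g2 = table.sum(axis=0)
    pA = (2 * g1[2] + g1[1]) / (2.0 * n)
    pB = (2 * g2[2] + g2[1]) / (2.0 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return float("nan")
    lo = max(-pA * pB, -(1 - pA) * (1 - pB))
    hi = min(pA * (1 - pB), (1 - pA) * pB)
    grid = np.linspace(lo, hi, n_grid)
    for _ in range(3):  # progressive refinement around the running argmax
        best = int(np.argmax(_grid_loglik(table, pA, pB, grid)))
        a = grid[max(best - 1, 0)]
        b = grid[min(best + 1, grid.size - 1)]
        grid = np.linspace(a, b, 1001)
    D = float(grid[int(np.argmax(_grid_loglik(table, pA, pB, grid)))])
    return float(D * D / (pA * (1 - pA) * pB * (1 - pB)))


def all_genotype_tables(max_n: int):
    """Yield every 3x3 genotype-count table with 2 <= total <= max_n."""
    for n in range(2, max_n + 1):
        for cells in itertools.combinations_with_replacement(range(9), n):
            table = np.zeros(9, dtype=int)
            for c in cells:
                table[c] += 1
            yield table.reshape(3, 3)


# -- Type II ANOVA via explicit regression ----------------------------------


def type2_anova_bruteforce(y, pop, sex):
    """Type II F tests for a 2x2 factorial, from raw RSS differences.

    Builds design matrices longhand (sum-to-zero coding) and compares
    residual sums of squares of nested least-squares fits.
    """
    y = np.asarray(y, dtype=float)
    a = np.where(np.asarray(pop) == sorted(set(pop))[0], 1.0, -1.0)
    b = np.where(np.asarray(sex) == sorted(set(sex))[0], 1.0, -1.0)
    ab = a * b
    one = np.ones_like(y)

    def rss(*cols):
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_full = rss(one, a, b, ab)
    rss_ab = rss(one, a, b)
    rss_a = rss(one, a)
    rss_b = rss(one, b)
    df_resid = y.size - 4
    mse = rss_full / df_resid
    out = {}
    for name, ss in (
        ("location", rss_b - rss_ab),   # SS(A | B)
        ("sex", rss_a - rss_ab),        # SS(B | A)
        ("interaction", rss_ab - rss_full),
    ):
        F = (ss / 1.0) / mse
        out[name] = F
    return out, df_resid


# -- Mendelian transmission for kinship -------------------------------------


def mendelian_family(freqs: np.ndarray, rng: np.random.Generator):
    """(parent1, parent2, child) genotype vectors from allele frequencies.

    Parents are unrelated Hardy-Weinberg draws; the child receives one
    uniformly chosen allele from each parent.
    """
    p1 = rng.binomial(2, freqs)
    p2 = rng.binomial(2, freqs)

    def gamete(g):
        # allele transmitted by a parent with genotype g (count of alt)
        out = np.where(g == 1, rng.integers(0, 2, g.size), g // 2)
        return out

    child = gamete(p1) + gamete(p2)
    return p1.astype(np.int8), p2.astype(np.int8), child.astype(np.int8)
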