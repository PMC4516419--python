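"""Nucleotide diversity and Watterson's theta under both denominators.

RADseq diversity is conventionally reported two ways: averaged over
polymorphic SNPs only (values of order 0.1-0.2) and per site including the
invariant majority of the sequenced fraction (values of order 1e-4-1e-3).
Both are exposed here.  Allele frequencies are always computed from the
non-missing chromosomes at each SNP (pairwise-complete), which preserves
sample size at low call rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import GenotypeMatrix, LocusCatalog


@dataclass
class DiversityResult:
    population: str
    pi_polymorphic: float
    pi_per_site: float
    theta_w_per_site: float
    n_polymorphic_loci: int
    total_sites: int


def _per_snp_diversity(matrix: GenotypeMatrix, rows: np.ndarray) -> np.ndarray:
    """Unbiased per-SNP heterozygosity 2*p*q*n/(n-1) from allele counts."""
    alt, n_chrom = matrix.allele_counts(rows)
    ok = n_chrom >= 2
    p = np.zeros_like(alt)
    p[ok] = alt[ok] / n_chrom[ok]
    pi = np.zeros_like(alt)
    pi[ok] = 2.0 * p[ok] * (1.0 - p[ok]) * n_chrom[ok] / (n_chrom[ok] - 1.0)
    pi[~ok] = np.nan
    return pi


def pi_per_snp(matrix: GenotypeMatrix, population: str) -> float:
    """Mean per-SNP unbiased diversity over all SNPs (polymorphic-only scale)."""
    rows = matrix.population_indices(population)
    pi = _per_snp_diversity(matrix, rows)
    if np.all(np.isnan(pi)):
        raise ValueError(f"no callable SNPs for population {population!r}")
    return float(np.nanmean(pi))


def pi_per_site(
    matrix: GenotypeMatrix, population: str, total_sites: int
) -> float:
    """Summed per-SNP diversity divided by the total sequenced sites.

    ``total_sites`` includes invariant sites and is supplied as a constant
    (the SNP matrix does not carry the invariant loci).
    """
    if total_sites <= 0:
        raise ValueError("total_sites must be positive")
    rows = matrix.population_indices(population)
    pi = _per_snp_diversity(matrix, rows)
    return float(np.nansum(pi) / total_sites)


def watterson_theta(
    matrix: GenotypeMatrix, population: str, total_sites: int
) -> float:
    """Watterson's theta per site: S / (a1 * total_sites).

    S counts sites segregating within the population (pairwise-complete);
    the harmonic number a1 uses the median non-missing chromosome count,
    which is robust to uneven per-SNP call rates.
    """
    if total_sites <= 0:
        raise ValueError("total_sites must be positive")
    rows = matrix.population_indices(population)
    alt, n_chrom = matrix.allele_counts(rows)
    ok = n_chrom >= 2
    if not ok.any():
        raise ValueError("need >=2 called chromosomes at >=1 SNP")
    seg = ok & (alt > 0) & (alt < n_chrom)
    S = int(seg.sum())
    if S == 0:
        return 0.0
    n = int(np.median(n_chrom[ok]))
    if n < 2:
        raise ValueError("median chromosome count < 2")
    a1 = np.sum(1.0 / np.arange(1, n))
    return float(S / (a1 * total_sites))


def diversity_report(
    matrix: GenotypeMatrix, catalog: LocusCatalog, total_sites: int | None = None
) -> list[DiversityResult]:
    """Per-population diversity summary (both denominators)."""
    if total_sites is None:
        total_sites = catalog.total_sites()
    results = []
    for pop in matrix.population_set:
        rows = matrix.population_indices(pop)
        alt, n_chrom = matrix.allele_counts(rows)
        seg = (n_chrom >= 2) & (alt > 0) & (alt < n_chrom)
        loci = {matrix.snp_ids[j][0] for j in np.flatnonzero(seg)}
        results.append(
            DiversityResult(
                population=pop,
                pi_polymorphic=pi_per_snp(matrix, pop),
                pi_per_site=pi_per_site(matrix, pop, total_sites),
                theta_w_per_site=watterson_theta(matrix, pop, total_sites),
                n_polymorphic_loci=len(loci),
                total_sites=total_sites,
            )
        )
    return results
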