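"""Declarative SNP-filtering protocols.

Seven presets reproduce the published data-set construction ladder: varying
individual subsampling, one-SNP-per-locus thinning, observed-heterozygosity
and minor-allele-frequency thresholds, and per-population completeness rules.

Rule semantics (documented order: subsample -> completeness ->
heterozygosity/MAF -> one SNP per locus):

* MAF is the frequency of the rarer allele pooled over all retained
  individuals (pairwise-complete allele counts); the filter keeps
  SNPs with MAF strictly > the threshold.
* Heterozygosity is the observed fraction of heterozygous genotypes among
  non-missing calls; the filter keeps SNPs strictly < the threshold.
* Completeness rules are evaluated per SNP from per-population non-missing
  fractions.
* One SNP per locus keeps the lowest-offset SNP of each locus.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .matrix import MISSING, GenotypeMatrix, LocusCatalog

COMPLETENESS_RULES = (
    "50pct_2pops",   # >=50% of individuals called in at least 2 populations
    "85pct_all",     # >=85% called in every population
    "100pct_all",    # every individual called in every population
)


@dataclass(frozen=True)
class FilterProtocol:
    """One data-set construction recipe."""

    name: str
    individuals_per_population: int | None = None  # None = all
    one_snp_per_locus: bool = False
    max_heterozygosity: float | None = None
    min_maf: float | None = None
    completeness_rule: str = "50pct_2pops"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.completeness_rule not in COMPLETENESS_RULES:
            raise ValueError(
                f"unknown completeness rule {self.completeness_rule!r}; "
                f"choose from {COMPLETENESS_RULES}"
            )
        for thr in (self.max_heterozygosity, self.min_maf):
            if thr is not None and not (0.0 <= thr <= 1.0):
                raise ValueError(f"threshold {thr} outside [0, 1]")


#: The published seven-protocol ladder (protocols 4-7 subsample 9 per colony).
PROTOCOLS: dict[int, FilterProtocol] = {
    1: FilterProtocol("1"),
    2: FilterProtocol("2", one_snp_per_locus=True),
    3: FilterProtocol("3", one_snp_per_locus=True, max_heterozygosity=0.75, min_maf=0.05),
    4: FilterProtocol("4", individuals_per_population=9, one_snp_per_locus=True),
    5: FilterProtocol(
        "5",
        individuals_per_population=9,
        one_snp_per_locus=True,
        max_heterozygosity=0.75,
        min_maf=0.05,
    ),
    6: FilterProtocol(
        "6",
        individuals_per_population=9,
        one_snp_per_locus=True,
        completeness_rule="85pct_all",
    ),
    7: FilterProtocol(
        "7",
        individuals_per_population=9,
        one_snp_per_locus=True,
        completeness_rule="100pct_all",
    ),
}


def subsample_individuals(
    matrix: GenotypeMatrix, k_per_pop: int, seed: int
) -> GenotypeMatrix:
    """Draw ``k_per_pop`` individuals per population uniformly, seeded."""
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for pop in matrix.population_set:
        idx = matrix.population_indices(pop)
        if k_per_pop > idx.size:
            raise ValueError(
                f"population {pop!r} has {idx.size} individuals, "
                f"cannot subsample {k_per_pop}"
            )
        chosen = rng.choice(idx, size=k_per_pop, replace=False)
        keep.extend(sorted(int(i) for i in chosen))
    return matrix.subset_individuals(keep)


def _completeness_mask(matrix: GenotypeMatrix, rule: str) -> np.ndarray:
    pops = matrix.population_set
    called_frac = np.empty((len(pops), matrix.n_snps))
    for pi, pop in enumerate(pops):
        rows = matrix.population_indices(pop)
        called_frac[pi] = np.mean(matrix.genotypes[rows] != MISSING, axis=0)
    if rule == "50pct_2pops":
        return (called_frac >= 0.5).sum(axis=0) >= min(2, len(pops))
    if rule == "85pct_all":
        return (called_frac >= 0.85).all(axis=0)
    if rule == "100pct_all":
        return (called_frac >= 1.0).all(axis=0)
    raise ValueError(f"unknown completeness rule {rule!r}")


def observed_heterozygosity(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-SNP fraction of heterozygotes among non-missing calls."""
    called = matrix.genotypes != MISSING
    n_called = called.sum(axis=0)
    n_het = (matrix.genotypes == 1).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n_called > 0, n_het / n_called, np.nan)


def minor_allele_frequency(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-SNP pooled minor-allele frequency (pairwise-complete)."""
    alt, n_chrom = matrix.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chrom > 0, alt / n_chrom, np.nan)
    return np.minimum(p, 1.0 - p)


def apply_protocol(
    matrix: GenotypeMatrix, catalog: LocusCatalog, protocol: FilterProtocol
) -> GenotypeMatrix:
    """Apply a filtering protocol; returns the filtered matrix."""
    out = matrix
    if protocol.individuals_per_population is not None:
        out = subsample_individuals(
            out, protocol.individuals_per_population, protocol.seed
        )
    keep = _completeness_mask(out, protocol.completeness_rule)
    if protocol.max_heterozygosity is not None:
        het = observed_heterozygosity(out)
        keep &= np.nan_to_num(het, nan=1.0) < protocol.max_heterozygosity
    if protocol.min_maf is not None:
        maf = minor_allele_frequency(out)
        keep &= np.nan_to_num(maf, nan=0.0) > protocol.min_maf
    out = out.subset_snps(np.flatnonzero(keep))
    if protocol.one_snp_per_locus:
        seen: dict[str, int] = {}
        for j, (locus, offset) in enumerate(out.snp_ids):
            # retain the lowest-offset SNP per locus; snp_ids are offset-sorted
            # within locus but guard against arbitrary input order
            if locus not in seen or offset < out.snp_ids[seen[locus]][1]:
                seen[locus] = j
        out = out.subset_snps(sorted(seen.values()))
    return out


def protocol_report(before: GenotypeMatrix, after: GenotypeMatrix) -> dict:
    """Summary of a filtering step: SNP/locus counts, completeness, per-pop n."""
    def loci(m: GenotypeMatrix) -> int:
        return len({l for l, _ in m.snp_ids})

    return {
        "snps_before": before.n_snps,
        "snps_after": after.n_snps,
        "loci_before": loci(before),
        "loci_after": loci(after),
        "completeness_before": before.completeness() if before.n_snps else float("nan"),
        "completeness_after": after.completeness() if after.n_snps else float("nan"),
        "individuals_per_population": {
            p: int(len(after.population_indices(p))) for p in after.population_set
        },
    }


def protocol_with_seed(protocol: FilterProtocol, seed: int) -> FilterProtocol:
    return replace(protocol, seed=seed)
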