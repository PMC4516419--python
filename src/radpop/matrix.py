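"""Core containers for RADseq SNP data.

Genotypes are diploid codes: 0 homozygous reference, 1 heterozygous,
2 homozygous alternate, ``MISSING`` (-1) for no call.  Reference/alternate
polarity is arbitrary (no outgroup), so every statistic downstream must be
invariant to relabelling the two alleles at any SNP.

Coordinates are 0-based half-open internally; VCF emission is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING: int = -1

VALID_CODES = frozenset({0, 1, 2, MISSING})


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs diploid genotype matrix with population labels.

    Parameters
    ----------
    individuals : sequence of str
        Individual identifiers (rows).
    populations : sequence of str
        Per-individual population label, same length as ``individuals``.
    genotypes : ndarray of shape (n_individuals, n_snps)
        Integer codes 0/1/2 with :data:`MISSING` for no-calls.
    snp_ids : sequence of (locus_id, offset)
        Per-SNP locus membership and 0-based offset within the locus.
    """

    individuals: list[str]
    populations: list[str]
    genotypes: np.ndarray
    snp_ids: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.individuals = list(self.individuals)
        self.populations = list(self.populations)
        self.snp_ids = [(str(l), int(o)) for l, o in self.snp_ids]
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x SNPs)")
        n, m = self.genotypes.shape
        if len(self.individuals) != n:
            raise ValueError(
                f"{len(self.individuals)} individual IDs for {n} genotype rows"
            )
        if len(self.populations) != n:
            raise ValueError("populations must match the number of individuals")
        if len(self.snp_ids) != m:
            raise ValueError(f"{len(self.snp_ids)} SNP IDs for {m} genotype columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.genotypes[i, j]} at ({i}, {j})"
            )

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def population_set(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.populations) == population)
        if idx.size == 0:
            raise KeyError(f"population {population!r} not present in matrix")
        return idx

    # -- slicing ----------------------------------------------------------

    def subset_individuals(self, indices: Iterable[int]) -> "GenotypeMatrix":
        idx = np.asarray(list(indices), dtype=int)
        return GenotypeMatrix(
            [self.individuals[i] for i in idx],
            [self.populations[i] for i in idx],
            self.genotypes[idx],
            self.snp_ids,
        )

    def subset_snps(self, indices: Iterable[int]) -> "GenotypeMatrix":
        idx = np.asarray(list(indices), dtype=int)
        return GenotypeMatrix(
            self.individuals,
            self.populations,
            self.genotypes[:, idx],
            [self.snp_ids[i] for i in idx],
        )

    def relabel_alleles(self, snp_indices: Iterable[int]) -> "GenotypeMatrix":
        """Swap reference/alternate at the given SNPs (code 0 <-> 2).

        Statistics are required to be invariant under this operation.
        """
        g = self.genotypes.copy()
        idx = np.asarray(list(snp_indices), dtype=int)
        col = g[:, idx]
        nonmiss = col != MISSING
        col[nonmiss] = 2 - col[nonmiss]
        g[:, idx] = col
        return GenotypeMatrix(self.individuals, self.populations, g, self.snp_ids)

    # -- statistics -------------------------------------------------------

    def completeness(self) -> float:
        """Fraction of non-missing cells, in [0, 1]."""
        if self.genotypes.size == 0:
            raise ValueError("completeness undefined for an empty matrix")
        return float(np.mean(self.genotypes != MISSING))

    def allele_counts(self, rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP (alt allele count, called chromosome count) over ``rows``."""
        g = self.genotypes if rows is None else self.genotypes[rows]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0).astype(float)
        n_chrom = 2.0 * called.sum(axis=0)
        return alt, n_chrom


@dataclass
class LocusCatalog:
    """Per-locus length (bp) and 0-based SNP offsets.

    Offsets must be strictly increasing and lie in ``[0, length)``.
    Monomorphic loci carry an empty offset tuple.
    """

    loci: dict[str, tuple[int, tuple[int, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus_id, (length, offsets) in self.loci.items():
            offsets = tuple(int(o) for o in offsets)
            if any(not (0 <= o < length) for o in offsets):
                raise ValueError(f"locus {locus_id}: offset out of [0, {length})")
            if any(b <= a for a, b in zip(offsets, offsets[1:])):
                raise ValueError(f"locus {locus_id}: offsets not strictly increasing")
            self.loci[locus_id] = (int(length), offsets)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.loci

    def __len__(self) -> int:
        return len(self.loci)

    def length(self, locus_id: str) -> int:
        return self.loci[locus_id][0]

    def offsets(self, locus_id: str) -> tuple[int, ...]:
        return self.loci[locus_id][1]

    def total_sites(self) -> int:
        return sum(length for length, _ in self.loci.values())


def population_map(matrix: GenotypeMatrix) -> dict[str, str]:
    """Individual ID -> population label mapping."""
    return dict(zip(matrix.individuals, matrix.populations))


def validate_population_map(matrix: GenotypeMatrix, popmap: Mapping[str, str]) -> None:
    """Check that a population map covers exactly the matrix rows."""
    missing = [i for i in matrix.individuals if i not in popmap]
    if missing:
        raise ValueError(f"individuals absent from population map: {missing[:5]}")
    if len(popmap) != matrix.n_individuals:
        raise ValueError(
            f"population map has {len(popmap)} entries for "
            f"{matrix.n_individuals} individuals"
        )
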