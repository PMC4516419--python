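"""Pairwise kinship screening with the KING-robust estimator.

The between-family (robust) estimator is used because it stays unbiased
under the very population structure the rest of the pipeline measures:

    phi_hat = (N_Aa,Aa - 2 * N_opp) / (N_Aa(i) + N_Aa(j))

over SNPs called in both individuals, where N_Aa,Aa counts SNPs at which
both are heterozygous, N_opp counts opposite homozygotes (0,2)/(2,0), and
N_Aa(.) counts heterozygous SNPs per individual.  Expected values: 0.5 for
duplicates, 0.25 for parent-offspring or full sibs, ~0 (often negative)
for unrelated pairs.  Degree classes split at 2^(-d-3/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import MISSING, GenotypeMatrix

#: degree-class boundaries 2^(-d-3/2) for d = 0, 1, 2
DUPLICATE_CUTOFF = 2.0 ** -1.5      # 0.3536
FIRST_DEGREE_CUTOFF = 2.0 ** -2.5   # 0.1768
SECOND_DEGREE_CUTOFF = 2.0 ** -3.5  # 0.0884

LOW_CONFIDENCE_SNPS = 100


@dataclass
class KinshipPair:
    id1: str
    id2: str
    n_snps: int
    kinship: float  # NaN when undefined (both individuals 0 heterozygosity)
    degree: str
    low_confidence: bool


def king_kinship(matrix: GenotypeMatrix, i: int, j: int) -> float:
    """KING-robust kinship coefficient between individuals ``i`` and ``j``."""
    gi, gj = matrix.genotypes[i], matrix.genotypes[j]
    shared = (gi != MISSING) & (gj != MISSING)
    if not shared.any():
        raise ValueError(
            f"individuals {matrix.individuals[i]!r} and "
            f"{matrix.individuals[j]!r} share no called SNPs"
        )
    a, b = gi[shared], gj[shared]
    n_het_i = int(np.sum(a == 1))
    n_het_j = int(np.sum(b == 1))
    if n_het_i + n_het_j == 0:
        return float("nan")
    n_both_het = int(np.sum((a == 1) & (b == 1)))
    n_opp = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
    return (n_both_het - 2.0 * n_opp) / (n_het_i + n_het_j)


def classify_degree(coefficient: float) -> str:
    """Degree class for a kinship coefficient (boundaries at 2^(-d-3/2))."""
    if not np.isfinite(coefficient):
        return "undefined"
    if coefficient > DUPLICATE_CUTOFF:
        return "duplicate"
    if coefficient > FIRST_DEGREE_CUTOFF:
        return "1st-degree"
    if coefficient > SECOND_DEGREE_CUTOFF:
        return "2nd-degree"
    return "unrelated"


def kinship_screen(matrix: GenotypeMatrix) -> list[KinshipPair]:
    """All pairwise kinship coefficients with degree classes.

    Pairs sharing fewer than :data:`LOW_CONFIDENCE_SNPS` SNPs are flagged.
    """
    pairs: list[KinshipPair] = []
    g = matrix.genotypes
    called = g != MISSING
    for i in range(matrix.n_individuals):
        for j in range(i + 1, matrix.n_individuals):
            n_shared = int(np.sum(called[i] & called[j]))
            phi = king_kinship(matrix, i, j) if n_shared else float("nan")
            pairs.append(
                KinshipPair(
                    matrix.individuals[i],
                    matrix.individuals[j],
                    n_shared,
                    phi,
                    classify_degree(phi),
                    n_shared < LOW_CONFIDENCE_SNPS,
                )
            )
    return pairs
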