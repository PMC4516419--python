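"""Demographic arithmetic: mutation rates, effective size and gene flow.

These are the deterministic conversions that turn coalescent-scaled
parameters into biological quantities: a per-year substitution rate times a
generation time gives the per-generation mutation rate; theta = 4*Ne*mu
inverts to Ne; and a mutation-scaled migration rate M = m/mu times the
receiving population's Theta gives the migrants-per-generation summary Nm.

Two Nm conventions are supported.  "literal" multiplies Theta by M
directly (Theta*M = 4*N*mu * m/mu = 4*N*m, the product convention used by
coalescent gene-flow reports); "diploid" divides by 4 to give N*m itself.
Reports print both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean

import numpy as np


@dataclass(frozen=True)
class DemographyParams:
    mu_per_year: float  # substitutions / site / year
    generation_time: float  # years
    locus_length: int = 90

    def __post_init__(self) -> None:
        if self.mu_per_year <= 0 or self.generation_time <= 0 or self.locus_length <= 0:
            raise ValueError("all demography parameters must be positive")


@dataclass
class MigrationEstimate:
    """One data set's coalescent gene-flow estimate."""

    dataset: str
    model: str  # "symmetric" | "nonsymmetric"
    theta_per_locus: dict[str, float]  # per deme
    M: dict[tuple[str, str], float]  # (receiving, source) -> m/mu


def mu_per_generation(params: DemographyParams) -> float:
    """Per-generation mutation rate = per-year rate x generation time."""
    return params.mu_per_year * params.generation_time


def theta_per_site(theta_per_locus: float, locus_length: int) -> float:
    """Convert a per-locus Theta to a per-bp value."""
    if locus_length <= 0:
        raise ValueError("locus_length must be positive")
    return theta_per_locus / locus_length


def ne_from_theta(theta_site: float, mu_generation: float) -> float:
    """Effective size from theta = 4*Ne*mu (both per site, per generation)."""
    if theta_site <= 0 or mu_generation <= 0:
        raise ValueError("theta and mu must be positive")
    return theta_site / (4.0 * mu_generation)


def nm_from_migrate(
    theta_receiving: float, M: float, convention: str = "literal"
) -> float:
    """Migrants per generation from Theta of the receiving deme and M = m/mu.

    convention "literal": Theta * M; "diploid": Theta * M / 4.
    For a symmetric model pass the mean Theta of the pair as
    ``theta_receiving``.
    """
    if theta_receiving <= 0:
        raise ValueError("theta must be positive")
    if M < 0:
        raise ValueError("M must be >= 0")
    if convention == "literal":
        return theta_receiving * M
    if convention == "diploid":
        return theta_receiving * M / 4.0
    raise ValueError(f"unknown convention {convention!r}")


def nm_to_fst(nm: float, n_demes: int = 2) -> float:
    """Island-model expectation FST = 1 / (1 + 4*Nm*(d/(d-1))^2)."""
    d = n_demes
    return 1.0 / (1.0 + 4.0 * nm * (d / (d - 1.0)) ** 2)


def nm_from_fst(fst: float, n_demes: int = 2) -> float:
    """Invert the island-model expectation: Nm from an observed FST."""
    if not (0.0 < fst < 1.0):
        raise ValueError("fst must be in (0, 1)")
    d = n_demes
    return (1.0 / fst - 1.0) / 4.0 * ((d - 1.0) / d) ** 2


def average_nm(
    estimates: list[MigrationEstimate],
    direction: tuple[str, str],
    convention: str = "literal",
    pools: dict[str, list[str]] | None = None,
) -> float:
    """Mean Nm for one direction over (data set x nonsymmetric model) entries.

    ``direction`` is (receiving, source) at the pooled level; ``pools`` maps
    a pooled label to its member demes (e.g. Hawaii = [Tern, Midway]), so a
    Hawaii -> Japan summary averages every member-pair entry.  Symmetric-
    model estimates are excluded (they carry no direction).
    """
    pools = pools or {}

    def expand(label: str) -> list[str]:
        return pools.get(label, [label])

    receiving, source = direction
    values: list[float] = []
    for est in estimates:
        if est.model != "nonsymmetric":
            continue
        for r in expand(receiving):
            for s in expand(source):
                if (r, s) in est.M:
                    values.append(
                        nm_from_migrate(est.theta_per_locus[r], est.M[(r, s)], convention)
                    )
    if not values:
        raise ValueError(f"no estimates for direction {direction}")
    return float(mean(values))
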