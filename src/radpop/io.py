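"""Reading and writing genotype matrices, locus catalogs and population maps.

Supported formats: VCF v4.2 (GT only, biallelic SNPs), a TSV genotype table
(individuals x SNPs; first two columns individual ID and population), the
STRUCTURE two-row-per-individual format, a catalog TSV
(locus_id, length, comma-separated offsets) and a two-column population map.

Locus membership of each SNP is carried in the VCF as CHROM = locus ID and
POS = offset + 1 (1-based on emission), with ID = "locusID_offset".
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np

from .matrix import MISSING, GenotypeMatrix, LocusCatalog

# cyvcf2 gt_types codes
_HOM_REF, _HET, _UNKNOWN, _HOM_ALT = 0, 1, 2, 3
_GT_CODE = {_HOM_REF: 0, _HET: 1, _HOM_ALT: 2, _UNKNOWN: MISSING}


def read_vcf(path: str, popmap: Mapping[str, str] | str | None = None) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    ``popmap`` may be a mapping of individual ID to population, a path to a
    two-column TSV, or None (every individual labelled ``"all"``).
    Multi-allelic records and records without GT are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    snp_ids: list[tuple[str, int]] = []
    for k, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise ValueError(
                f"record {k} ({rec.CHROM}:{rec.POS}) is not biallelic "
                f"(ALT={rec.ALT})"
            )
        if rec.gt_types is None or len(rec.gt_types) != len(samples):
            raise ValueError(f"record {k} ({rec.CHROM}:{rec.POS}) lacks GT calls")
        codes = np.array([_GT_CODE[t] for t in rec.gt_types], dtype=np.int8)
        columns.append(codes)
        locus_id, offset = _snp_identity(rec.ID, rec.CHROM, rec.POS)
        snp_ids.append((locus_id, offset))
    vcf.close()
    if popmap is None:
        populations = ["all"] * len(samples)
    else:
        if isinstance(popmap, str):
            popmap = read_population_map(popmap)
        populations = [popmap[s] for s in samples]
    genotypes = (
        np.column_stack(columns)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, populations, genotypes, snp_ids)


def _snp_identity(rec_id: str | None, chrom: str, pos: int) -> tuple[str, int]:
    # Prefer an explicit "locusID_offset" ID; fall back to CHROM/POS.
    if rec_id and rec_id != "." and "_" in rec_id:
        locus, _, off = rec_id.rpartition("_")
        if off.isdigit():
            return locus, int(off)
    return chrom, pos - 1


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write the matrix as a minimal VCF v4.2 (GT only, alleles A/C)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for locus in dict.fromkeys(l for l, _ in matrix.snp_ids):
            fh.write(f"##contig=<ID={locus}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.individuals)
            + "\n"
        )
        for j, (locus, offset) in enumerate(matrix.snp_ids):
            calls = "\t".join(gt_str[int(g)] for g in matrix.genotypes[:, j])
            fh.write(f"{locus}\t{offset + 1}\t{locus}_{offset}\tA\tC\t.\tPASS\t.\tGT\t{calls}\n")


def completeness(matrix: GenotypeMatrix) -> float:
    """Fraction of non-missing genotype cells (0-1)."""
    return matrix.completeness()


def snp_spectrum(matrix: GenotypeMatrix, catalog: LocusCatalog) -> dict[int, int]:
    """Histogram of SNPs per polymorphic locus, e.g. ``{1: 2234, 2: 418}``.

    Counts sum to the number of loci carrying at least one SNP in the
    matrix.  Raises if a SNP references a locus absent from the catalog.
    """
    per_locus: dict[str, int] = {}
    for locus, offset in matrix.snp_ids:
        if locus not in catalog:
            raise KeyError(f"SNP {locus}_{offset} references unknown locus {locus!r}")
        per_locus[locus] = per_locus.get(locus, 0) + 1
    spectrum: dict[int, int] = {}
    for count in per_locus.values():
        spectrum[count] = spectrum.get(count, 0) + 1
    return dict(sorted(spectrum.items()))


def export_structure(matrix: GenotypeMatrix, path: str) -> None:
    """Write the STRUCTURE two-row-per-individual format; missing is -9.

    Each diploid contributes two allele rows (0/1 coding); population
    labels are emitted as 1-based integers in column 2.
    """
    pop_code = {p: i + 1 for i, p in enumerate(matrix.population_set)}
    rows = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (-9, -9)}
    with open(path, "w") as fh:
        for i, ind in enumerate(matrix.individuals):
            alleles = [rows[int(g)] for g in matrix.genotypes[i]]
            for k in (0, 1):
                line = [ind, str(pop_code[matrix.populations[i]])]
                line += [str(a[k]) for a in alleles]
                fh.write("\t".join(line) + "\n")


# -- TSV genotype table ----------------------------------------------------


def write_genotype_tsv(matrix: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        header = ["individual", "population"] + [
            f"{l}_{o}" for l, o in matrix.snp_ids
        ]
        fh.write("\t".join(header) + "\n")
        for i, ind in enumerate(matrix.individuals):
            row = [ind, matrix.populations[i]] + [
                str(int(g)) for g in matrix.genotypes[i]
            ]
            fh.write("\t".join(row) + "\n")


def read_genotype_tsv(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        snp_ids = []
        for col in header[2:]:
            locus, _, off = col.rpartition("_")
            snp_ids.append((locus, int(off)))
        individuals, populations, rows = [], [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            individuals.append(parts[0])
            populations.append(parts[1])
            rows.append([int(x) for x in parts[2:]])
    return GenotypeMatrix(individuals, populations, np.array(rows, dtype=np.int8), snp_ids)


# -- catalog and population map --------------------------------------------


def write_catalog_tsv(catalog: LocusCatalog, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tlength\toffsets\n")
        for locus_id, (length, offsets) in catalog.loci.items():
            fh.write(f"{locus_id}\t{length}\t{','.join(map(str, offsets))}\n")


def read_catalog_tsv(path: str) -> LocusCatalog:
    loci: dict[str, tuple[int, tuple[int, ...]]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            locus_id, length, offsets = line.rstrip("\n").split("\t")
            offs = tuple(int(o) for o in offsets.split(",")) if offsets else ()
            loci[locus_id] = (int(length), offs)
    return LocusCatalog(loci)


def write_population_map(popmap: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for ind, pop in popmap.items():
            fh.write(f"{ind}\t{pop}\n")


def read_population_map(path: str) -> dict[str, str]:
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            ind, pop = line.split()[:2]
            popmap[ind] = pop
    return popmap
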