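"""End-to-end orchestration: simulate -> filter (x7) -> statistics -> reports.

A single global seed fans out deterministically to per-stage seeds through
``numpy.random.SeedSequence`` (stage keys are hashed in a fixed order), so
each stage is independently reproducible and the whole run is byte-stable
under a fixed configuration.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from .demography import DemographyParams, mu_per_generation, ne_from_theta
from .diversity import diversity_report
from .filtering import PROTOCOLS, apply_protocol, protocol_report, protocol_with_seed
from .fst import dapc_lite, fst_matrix
from .io import (
    read_catalog_tsv,
    read_vcf,
    write_catalog_tsv,
    write_population_map,
    write_vcf,
)
from .kinship import kinship_screen
from .ld import pairwise_r2, smooth_decay
from .matrix import GenotypeMatrix, LocusCatalog, population_map
from .morphology import anova_report
from .simulate import (
    apply_dropout,
    default_morph_model,
    simulate_dataset,
    simulate_morphology,
    three_colony_model,
)

_STAGES = (
    "simulate",
    "dropout",
    "filter",
    "fst",
    "ld",
    "kinship",
    "morphology",
)


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from one global seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % 2**31)
        for stage, child in zip(_STAGES, children)
    }


DEFAULT_CONFIG = {
    "simulate": {"n_loci": 1500, "theta_per_site": 0.0006, "dropout": 0.196},
    "protocols": [1, 2, 3, 4, 5, 6, 7],
    "n_permutations": 99,
    "ld": {"k_subsample": 8, "span": 0.75},
    "demography": {"mu_per_year": 1.5e-9, "generation_time": 18.0},
    "seed": 0,
}


def run_pipeline(config: dict | None = None, out_dir: str = "radpop_out") -> dict:
    """Run the full pipeline and write TSV reports plus a manifest.

    Returns a dict of in-memory results keyed by stage.  Any stage failure
    raises with the stage name prefixed.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    os.makedirs(out_dir, exist_ok=True)
    seeds = stage_seeds(int(cfg["seed"]))
    results: dict = {}
    stage = "input"
    try:
        if "input_vcf" in cfg:
            matrix = read_vcf(cfg["input_vcf"], cfg.get("popmap"))
            catalog = read_catalog_tsv(cfg["catalog"])
        else:
            stage = "simulate"
            sim = cfg["simulate"]
            model = three_colony_model(
                n_loci=int(sim.get("n_loci", 1500)),
                seed=seeds["simulate"],
                theta_per_site=float(sim.get("theta_per_site", 0.0006)),
            )
            matrix, catalog = simulate_dataset(model)
            stage = "dropout"
            matrix = apply_dropout(matrix, float(sim.get("dropout", 0.0)), seeds["dropout"])
            write_vcf(matrix, os.path.join(out_dir, "simulated.vcf"))
            write_catalog_tsv(catalog, os.path.join(out_dir, "catalog.tsv"))
            write_population_map(
                population_map(matrix), os.path.join(out_dir, "popmap.tsv")
            )
        results["matrix"], results["catalog"] = matrix, catalog

        stage = "filter"
        demo = DemographyParams(**cfg["demography"])
        mu_gen = mu_per_generation(demo)
        per_protocol = []
        filtered: dict[int, GenotypeMatrix] = {}
        for num in cfg["protocols"]:
            proto = protocol_with_seed(PROTOCOLS[num], seeds["filter"] + num)
            fm = apply_protocol(matrix, catalog, proto)
            filtered[num] = fm
            rep = protocol_report(matrix, fm)
            row = {"protocol": num, **{k: v for k, v in rep.items() if not isinstance(v, dict)}}
            if fm.n_snps > 0:
                for d in diversity_report(fm, catalog):
                    row[f"pi_site_{d.population}"] = d.pi_per_site
                    row[f"theta_w_{d.population}"] = d.theta_w_per_site
                    row[f"ne_{d.population}"] = ne_from_theta(
                        max(d.theta_w_per_site, 1e-12), mu_gen
                    )
            per_protocol.append(row)
        protocol_df = pd.DataFrame(per_protocol)
        protocol_df.to_csv(os.path.join(out_dir, "protocol_summary.tsv"), sep="\t", index=False)
        results["protocols"] = {"table": protocol_df, "matrices": filtered}

        stage = "fst"
        base = filtered.get(1, matrix)
        fsts = fst_matrix(base, n_perm=int(cfg["n_permutations"]), seed=seeds["fst"])
        fst_rows = [
            {
                "popA": pair[0],
                "popB": pair[1],
                "fst": res.fst_global,
                "p_value": res.p_value,
                "n_snps": len(res.snp_ids),
            }
            for pair, res in fsts.items()
        ]
        pd.DataFrame(fst_rows).to_csv(
            os.path.join(out_dir, "fst.tsv"), sep="\t", index=False
        )
        results["fst"] = fsts
        dapc = dapc_lite(base, n_pcs=3, n_axes=2)
        coords = pd.DataFrame(
            {
                "individual": base.individuals,
                "population": base.populations,
                "ld1": dapc.coordinates[:, 0],
                "ld2": dapc.coordinates[:, 1],
            }
        )
        coords.to_csv(os.path.join(out_dir, "dapc_coordinates.tsv"), sep="\t", index=False)
        results["dapc"] = dapc

        stage = "ld"
        ld_cfg = cfg["ld"]
        ld_rows = []
        for pop in base.population_set:
            res = pairwise_r2(
                base, catalog, pop, int(ld_cfg["k_subsample"]), seeds["ld"]
            )
            for locus, o1, o2, dist, r2 in res.records:
                ld_rows.append(
                    {"population": pop, "locus": locus, "offset1": o1,
                     "offset2": o2, "distance": dist, "r2": r2}
                )
            results.setdefault("ld", {})[pop] = res
        pd.DataFrame(ld_rows).to_csv(os.path.join(out_dir, "ld_pairs.tsv"), sep="\t", index=False)

        stage = "kinship"
        pairs = kinship_screen(base)
        pd.DataFrame([asdict(p) for p in pairs]).to_csv(
            os.path.join(out_dir, "kinship.tsv"), sep="\t", index=False
        )
        results["kinship"] = pairs

        stage = "morphology"
        morph = simulate_morphology(default_morph_model(seed=seeds["morphology"]))
        morph.to_csv(os.path.join(out_dir, "morphology.tsv"), sep="\t", index=False)
        traits = [c for c in morph.columns if c not in ("specimen", "population", "sex")]
        aov = anova_report(morph, traits)
        aov.to_csv(os.path.join(out_dir, "morphology_anova.tsv"), sep="\t", index=False)
        results["morphology"] = {"table": morph, "anova": aov}

        stage = "manifest"
        manifest = {
            "radpop_version": __version__,
            "seed": int(cfg["seed"]),
            "stage_seeds": seeds,
            "config": {k: v for k, v in cfg.items() if k != "seed"},
            "conventions": {
                "missing_sentinel": -1,
                "fst_estimator": "weir_cockerham_1984_ratio_of_sums",
                "p_value": "(1 + #{null >= obs}) / (n_perm + 1)",
                "maf_pooling": "pooled over retained individuals",
                "one_snp_per_locus": "lowest offset",
                "nm_convention": "literal (Theta x M); diploid variant = /4",
                "ld_estimator": "EM haplotype frequencies",
                "anova_ss": "Type II",
            },
        }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        results["manifest"] = manifest
    except Exception as err:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return results
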