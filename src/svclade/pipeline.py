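"""End-to-end orchestration: simulate -> merge -> phylo-filter -> annotate
-> popgen -> date-ltr -> associate, with plain-file handoff between stages.

Every stage reads and writes ordinary VCF/TSV/YAML/JSON files inside the
output directory, logs its input/output record counts, and contributes an
entry to a run manifest. Identical config + seed gives byte-identical
text outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, io, ltr, merge, phylo, popgen, repeats, simulate

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_clade_A": 8,
        "n_clade_B": 24,
        "m_variants": 2000,
        "fp_cross_clade_rate": 0.05,
        "genotyping_error_rate": 0.01,
        "missing_rate": 0.0,
    },
    "merge": {"preset": "sr", "n_callers": 3, "jitter_sd": 50.0, "dropout": 0.1},
    "phylo_filter": {"tolerances": None},  # None -> clade-map defaults (4 / 2)
    "popgen": {"percentile": 99.0, "window": 1_000_000, "fst_pops": ["B_pop1", "B_pop2"]},
    "date_ltr": {"age_myr": 0.5, "ltr_len": 296, "mu": 0.0158},
    "associate": {"additive_effect": -1.0, "dominance_effect": 0.0, "noise_sd": 0.5},
}


def _merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(config: dict | None, outdir: str | Path, seed: int | None = None) -> dict:
    """Run every stage in dependency order; returns the manifest."""
    cfg = _merge_config(config)
    if seed is not None:
        cfg["seed"] = seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg["seed"], "stages": {}}

    def log_stage(name: str, t0: float, counts: dict, outputs: dict) -> None:
        manifest["stages"][name] = {
            "counts": counts,
            "outputs": {k: str(Path(v).relative_to(outdir)) for k, v in outputs.items()},
        }
        logger.info("stage=%s counts=%s wall=%.2fs", name, counts, time.time() - t0)

    # --- simulate -----------------------------------------------------
    t0 = time.time()
    sim_cfg = cfg["simulate"]
    params = simulate.SimulationParams(seed=cfg["seed"], **sim_cfg)
    cohort = simulate.simulate_cohort(params)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "truth": outdir / "truth.tsv",
        "repeats": outdir / "repeats.tsv",
        "clades": outdir / "clades.yaml",
        "chroms": outdir / "chroms.tsv",
    }
    io.write_sv_vcf(cohort.records, cohort.genotypes, paths["vcf"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    io.write_repeat_table(cohort.repeat_matches, paths["repeats"])
    cohort.clade_map.to_yaml(paths["clades"])
    io.write_chrom_table(cohort.chrom_table, paths["chroms"])
    log_stage("simulate", t0, {"variants": len(cohort.records)}, paths)

    # --- merge (consensus over jittered pseudo-caller replicates) -----
    t0 = time.time()
    mcfg = cfg["merge"]
    call_sets = simulate.make_caller_replicates(
        cohort.records,
        n_callers=mcfg["n_callers"],
        jitter_sd=mcfg["jitter_sd"],
        dropout=mcfg["dropout"],
        seed=cfg["seed"] + 1,
    )
    preset = merge.PRESETS[mcfg["preset"]]
    merged = merge.merge_call_sets(
        call_sets,
        max_dist=preset.max_dist,
        require_type_match=preset.require_type_match,
        min_callers=preset.min_callers,
        min_size=preset.min_size,
    )
    merged_path = outdir / "merged.tsv"
    pd.DataFrame(
        {
            "chrom": [m.representative.chrom for m in merged],
            "pos": [m.representative.pos for m in merged],
            "id": [m.representative.id for m in merged],
            "svtype": [m.representative.svtype for m in merged],
            "svlen": [m.representative.svlen for m in merged],
            "n_callers": [m.support_count for m in merged],
        }
    ).to_csv(merged_path, sep="\t", index=False)
    log_stage(
        "merge",
        t0,
        {"input_calls": sum(len(cs.records) for cs in call_sets), "merged": len(merged)},
        {"merged": merged_path},
    )

    # --- phylo-filter -------------------------------------------------
    t0 = time.time()
    clade_map = cohort.clade_map
    tol = cfg["phylo_filter"]["tolerances"]
    if tol is not None:
        clade_map = io.CladeMap(clade_map.assignments, tol)
    verdicts, retained_by_clade, union = phylo.apply_phylo_filter(cohort.genotypes, clade_map)
    verdicts_path = outdir / "verdicts.tsv"
    phylo.verdicts_to_frame(verdicts).to_csv(verdicts_path, sep="\t", index=False)
    retained_records = [r for r in cohort.records if r.id in union]
    retained_matrix = cohort.genotypes.subset_variants([r.id for r in retained_records])
    retained_vcf = outdir / "retained.vcf"
    io.write_sv_vcf(retained_records, retained_matrix, retained_vcf)
    summary_path = outdir / "retention_summary.tsv"
    phylo.retention_summary(verdicts, cohort.records, cohort.chrom_table).to_csv(
        summary_path, sep="\t", index=False
    )
    log_stage(
        "phylo_filter",
        t0,
        {"input": len(cohort.records), "retained": len(retained_records),
         "retained_percent": round(phylo.retention_percent(len(cohort.records), len(retained_records)), 2)},
        {"verdicts": verdicts_path, "retained_vcf": retained_vcf, "summary": summary_path},
    )

    # --- annotate -----------------------------------------------------
    t0 = time.time()
    assignments = repeats.assign_best_repeat(
        cohort.repeat_matches, variant_ids=[r.id for r in retained_records]
    )
    assignments = {vid: a for vid, a in assignments.items() if vid in union}
    comp = repeats.class_composition(assignments)
    comp_path = outdir / "repeat_composition.tsv"
    comp.to_csv(comp_path, sep="\t", index=False)
    log_stage("annotate", t0, {"assigned": len(assignments)}, {"composition": comp_path})

    # --- popgen -------------------------------------------------------
    t0 = time.time()
    pcfg = cfg["popgen"]
    grouping = {vid: a.repeat_class for vid, a in assignments.items()}
    clade_b_matrix = retained_matrix.subset_individuals(clade_map.members("B"))
    spectra = popgen.folded_afs(clade_b_matrix, grouping)
    afs_path = outdir / "afs.tsv"
    popgen.afs_to_frame(spectra).to_csv(afs_path, sep="\t", index=False)
    pop_of = {s: clade_map.population_of(s) for s in retained_matrix.individual_ids}
    fst_results = popgen.fst_scan(retained_matrix, pop_of, pops=pcfg["fst_pops"])
    fst_path = outdir / "fst.tsv"
    popgen.fst_to_frame(fst_results).to_csv(fst_path, sep="\t", index=False)
    defined = [r for r in fst_results if r.defined]
    outliers = popgen.fst_outliers(defined, percentile=pcfg["percentile"]) if len(defined) >= 2 else set()
    by_id = {r.id: r for r in retained_records}
    outlier_bed = outdir / "fst_outliers.bed"
    io.write_bed(
        sorted((by_id[v].chrom, by_id[v].pos - 1, by_id[v].interval[1]) for v in outliers),
        outlier_bed,
    )
    windows = popgen.window_density(retained_records, cohort.chrom_table, window=pcfg["window"])
    windows_path = outdir / "window_density.tsv"
    windows.to_csv(windows_path, sep="\t", index=False)
    pca = popgen.genotype_pca(retained_matrix, n_components=4)
    pca_path = outdir / "pca.tsv"
    pca_df = pd.DataFrame(
        pca.coordinates, columns=[f"PC{j + 1}" for j in range(pca.coordinates.shape[1])]
    )
    pca_df.insert(0, "individual", pca.individual_ids)
    pca_df.to_csv(pca_path, sep="\t", index=False, float_format="%.6g")
    log_stage(
        "popgen",
        t0,
        {"fst_defined": len(defined), "outliers": len(outliers)},
        {"afs": afs_path, "fst": fst_path, "outliers": outlier_bed, "windows": windows_path, "pca": pca_path},
    )

    # --- date-ltr -----------------------------------------------------
    t0 = time.time()
    dcfg = cfg["date_ltr"]
    left, right = simulate.simulate_ltr_pair(
        dcfg["age_myr"], ltr_len=dcfg["ltr_len"], rate_per_site_per_myr=dcfg["mu"], seed=cfg["seed"] + 2
    )
    pair = ltr.count_ltr_differences(left, right)
    est = ltr.estimate_insertion_age(pair.k, pair.L, ltr.DatingParams(mu=dcfg["mu"]))
    dating_path = outdir / "ltr_dating.tsv"
    pd.DataFrame(
        [{"k": est.k, "L": est.L, "mu": est.mu, "age_myr": est.age_myr, "age_years": est.age_years}]
    ).to_csv(dating_path, sep="\t", index=False)
    log_stage("date_ltr", t0, {"k": est.k, "age_myr": round(est.age_myr, 4)}, {"dating": dating_path})

    # --- associate ----------------------------------------------------
    t0 = time.time()
    acfg = cfg["associate"]
    # focus locus: the strongest defined differentiation signal
    if defined:
        focus = max(defined, key=lambda r: (np.nan_to_num(r.theta_hat, nan=-np.inf), r.variant_id))
        focus_id = focus.variant_id
    else:
        focus_id = retained_matrix.variant_ids[0]
    dos = retained_matrix.row(focus_id)
    pheno = simulate.simulate_phenotypes(
        dos,
        additive_effect=acfg["additive_effect"],
        dominance_effect=acfg["dominance_effect"],
        noise_sd=acfg["noise_sd"],
        seed=cfg["seed"] + 3,
        individual_ids=retained_matrix.individual_ids,
    )
    coded = assoc.code_genotypes(
        dos[dos != io.MISSING], individual_ids=list(pheno["individual"])
    )
    fit_add = assoc.expression_association(pheno["phenotype"], coded, include_dominance=False)
    fit_dom = assoc.expression_association(pheno["phenotype"], coded, include_dominance=True)
    comparison = assoc.compare_models(fit_dom, fit_add)
    assoc_path = outdir / "association.json"
    with open(assoc_path, "w") as fh:
        json.dump(
            {
                "variant_id": focus_id,
                "additive_fit": {"aicc": fit_add.aicc, "bic": fit_add.bic, "r_squared": fit_add.r_squared},
                "additive_dominance_fit": {"aicc": fit_dom.aicc, "bic": fit_dom.bic, "r_squared": fit_dom.r_squared},
                "delta_aicc": comparison.delta_aicc,
                "delta_bic": comparison.delta_bic,
                "dominance_model_selected": comparison.candidate_selected,
            },
            fh,
            indent=2,
        )
    log_stage("associate", t0, {"n": fit_add.n}, {"association": assoc_path})

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
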