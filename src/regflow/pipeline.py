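"""End-to-end orchestration over a synthetic fixture.

`run_all` generates every input with planted ground truth, chains all
five stages, and writes each stage's TSV outputs plus a JSON manifest.
All randomness flows from the single config seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from regflow import dge, enrichment, gwas_genes, io, regulators, simulate, twas_meta

logger = logging.getLogger("regflow")


def simulate_inputs(config: io.RunConfig, outdir: Path) -> dict[str, Path]:
    """Write the full synthetic input bundle and ground_truth.json."""
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    genes = simulate.simulate_gene_models(200, seed=seed)
    signal_loci = [("G00000", 8, 4.0), ("G00010", 6, 4.0)]
    snps = simulate.simulate_gwas(genes, 4000, signal_loci, seed=seed + 1)

    stats_table, gt_twas = simulate.simulate_twas_tables(
        n_genes=800, n_regions=8, n_up=25, n_down=25,
        effect_mu=4.0, seed=seed + 2,
    )
    sets, gt_sets = simulate.simulate_gene_sets(
        gt_twas, sorted(stats_table["gene_id"].unique()), n_random_sets=15,
        seed=seed + 3,
    )

    planted_de = {("G00000", "male"): 2.0, ("G00000", "female"): -2.0,
                  ("G00001", "male"): 1.5, ("G00002", "female"): 1.5}
    counts, meta, gt_counts = simulate.simulate_counts(
        n_genes=400,
        samples_per_arm={("male", "region01"): 8, ("female", "region01"): 8},
        planted_de=planted_de,
        seed=seed + 4,
    )

    regulons, network, tpm, gt_reg = simulate.simulate_regulatory_layer(
        n_tfs=6, targets_per_tf=12, n_candidates=8, n_intermediates=10,
        planted_mrs={"C00": "active"}, max_depth=2,
        n_unexpressed_decoys=2, seed=seed + 5,
    )

    gt = simulate.merge_ground_truth(gt_twas, gt_sets, gt_counts, gt_reg)

    paths = {
        "gene_models": outdir / "gene_models.tsv",
        "summary_stats": outdir / "summary_stats.tsv",
        "gene_stats": outdir / "twas_gene_stats.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "counts": outdir / "counts.tsv",
        "sample_meta": outdir / "sample_meta.tsv",
        "regulons": outdir / "regulons.tsv",
        "network_edges": outdir / "network_edges.tsv",
        "network_roles": outdir / "network_roles.tsv",
        "tpm": outdir / "tpm.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    io.write_gene_models(genes, paths["gene_models"])
    io.write_summary_stats(snps, paths["summary_stats"])
    io.write_gene_stats(stats_table, paths["gene_stats"])
    io.write_gmt(sets, paths["gene_sets"])
    io.write_counts(counts, paths["counts"])
    io.write_table(meta, paths["sample_meta"])
    io.write_regulons(regulons, paths["regulons"])
    io.write_signed_network(network, paths["network_edges"], paths["network_roles"])
    io.write_table(tpm, paths["tpm"])
    gt.to_json(paths["ground_truth"])
    return paths


def run_all(config: io.RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate inputs and run every stage; returns output paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = simulate_inputs(config, outdir / "inputs")

    out: dict[str, Path] = {}

    # stage 1: GWAS gene aggregation
    snps = io.read_summary_stats(inputs["summary_stats"])
    genes = io.read_gene_models(inputs["gene_models"])
    catalogue, gene_level = gwas_genes.run_gwas_genes(
        snps, genes, snp_p=config.snp_p, window_bp=config.window_bp,
        alpha=config.gene_alpha,
    )
    out["snp_catalogue"] = outdir / "snp_catalogue.tsv"
    out["gene_level"] = outdir / "gene_level.tsv"
    io.write_table(catalogue, out["snp_catalogue"])
    io.write_table(gene_level, out["gene_level"])

    # stage 2: TWAS meta-analysis
    stats_table = io.read_gene_stats(inputs["gene_stats"])
    meta_table = twas_meta.run_twas_meta(
        stats_table, min_regions=config.min_regions,
        alpha=config.consistency_alpha, meta_alpha=config.meta_alpha,
    )
    out["twas_meta"] = outdir / "twas_meta.tsv"
    io.write_table(meta_table, out["twas_meta"])

    # stage 3: enrichment of the cross-region mean-z signature
    sets = io.read_gmt(inputs["gene_sets"])
    mean_z = stats_table.groupby("gene_id")["zscore"].mean()
    mean_r2 = stats_table.groupby("gene_id")["cv_r2"].mean()
    enr = enrichment.enrich_catalogue(
        mean_z.to_dict(), sets, weights=mean_r2.to_dict(),
        mode="regression", n_perm=config.n_perm, seed=config.seed,
        min_size=config.min_set_size, max_size=config.max_set_size,
    )
    out["enrichment"] = outdir / "enrichment.tsv"
    io.write_table(enr, out["enrichment"])

    # stage 4: sex-stratified DGE + concordance
    counts = io.read_counts(inputs["counts"])
    sample_meta = io.read_sample_meta(inputs["sample_meta"])
    covariates = [c for c in ("age", "PMI", "pH", "RIN") if c in sample_meta.columns]
    strata, deg_summary = dge.run_stratified(
        counts, sample_meta, covariates, min_cpm=config.min_cpm,
        soft=(config.deg_soft_lfc, config.deg_soft_p),
        strict=(config.deg_strict_lfc, config.deg_strict_p),
        dataset="synthetic",
    )
    for key, table in strata.items():
        p = outdir / ("dge_" + "_".join(key) + ".tsv")
        out[f"dge_{'_'.join(key)}"] = p
        io.write_table(table, p)
    out["deg_summary"] = outdir / "deg_summary.tsv"
    io.write_table(deg_summary, out["deg_summary"])
    conc, conc_summary = dge.direction_concordance(meta_table, strata)
    out["concordance"] = outdir / "concordance.tsv"
    io.write_table(conc, out["concordance"])

    # stage 5: TF activity + master regulators on the regulatory layer
    regulons = io.read_regulons(inputs["regulons"])
    network = io.read_signed_network(inputs["network_edges"], inputs["network_roles"])
    tpm = io.read_tpm(inputs["tpm"])
    gt = simulate.GroundTruth.from_json(inputs["ground_truth"])
    signature = simulate.signature_from_tf_states(
        regulons, gt, seed=config.seed + 6
    )
    expressed = set(tpm.loc[tpm["tpm"] > config.tpm_min, "gene_id"])
    deg_genes = {
        g
        for table in strata.values()
        for g in table.loc[table["soft_deg"], "gene_id"]
    }
    twas_genes = set(meta_table.loc[meta_table["meta_selected"], "gene_id"])
    # planted regulator ids are part of the synthetic support universe
    twas_genes |= set(gt.planted_mrs)
    mr_long, mr_matrix = regulators.run_regulators(
        {"twas_region01": signature},
        regulons, network, {"twas_region01": expressed},
        twas_genes=twas_genes, deg_genes=deg_genes,
        n_perm=config.n_perm, seed=config.seed,
        tf_alpha=config.tf_alpha, max_len=config.max_path_len,
        min_score=config.min_score,
    )
    out["mr_results"] = outdir / "mr_results.tsv"
    out["mr_state_matrix"] = outdir / "mr_state_matrix.tsv"
    io.write_table(mr_long, out["mr_results"])
    io.write_table(mr_matrix, out["mr_state_matrix"])

    io.write_manifest(
        outdir / "manifest.json",
        command="run-all",
        config=config,
        inputs={k: str(v) for k, v in inputs.items()},
        outputs={k: str(v) for k, v in out.items()},
    )
    out["manifest"] = outdir / "manifest.json"
    return out
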