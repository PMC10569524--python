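"""End-to-end orchestration: simulate -> QC -> DE -> burden/enrichment ->
signatures -> reversal -> phenotype statistics -> report.

Every stage is a pure function of the configuration; all randomness is routed
through per-stage seeds derived from the config, so reruns with the same
config produce byte-identical TSV outputs.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import clip as clip_mod
from . import io as io_mod
from . import pheno as pheno_mod
from . import qc as qc_mod
from . import reversal as rev_mod
from . import synthdata
from . import vulnerability as vuln_mod
from .config import RunConfig
from .de import apply_thresholds, de_table

log = logging.getLogger("celltype_perturb")


def summarize_events(tables: list[pd.DataFrame]) -> dict:
    """Count DE events over a collection of per-population tables.

    An event is one significant (gene, population) pair; a gene significant
    in several populations contributes several events but one unique gene.
    """
    if not tables:
        raise ValueError("at least one table is required")
    sig = pd.concat([t[t["significant"]] for t in tables], ignore_index=True)
    n_events = len(sig)
    n_down = int((sig["direction"] == "down").sum())
    n_up = n_events - n_down
    return {
        "n_events": n_events,
        "n_unique_genes": int(sig["gene"].nunique()),
        "n_down": n_down,
        "n_up": n_up,
        "frac_down": round(n_down / n_events, 4) if n_events else 0.0,
        "mean_abs_log2fc": (round(float(np.abs(sig["log2fc"]).mean()), 4)
                            if n_events else 0.0),
    }


def run_pipeline(config: RunConfig, outdir: str) -> dict:
    """Run every stage and write tables, a summary JSON, and a log file.

    Returns the summary dictionary.
    """
    os.makedirs(outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {}
    try:
        sim = config.sim.validate()
        config.to_yaml(os.path.join(outdir, "config.yaml"))
        log.info("seed=%d thresholds: lfc>=%.4g fdr<%.4g relaxed lfc>=%.4g fdr<%.4g "
                 "burden n=%d seed=%d k=%d tau<%.4g",
                 sim.seed, config.lfc_min, config.fdr_max, config.lfc_min_relaxed,
                 config.fdr_max_relaxed, config.burden_n_cells, config.burden_seed,
                 config.signature_k, config.candidate_tau)

        # --- simulate ------------------------------------------------------
        adata, truth = synthdata.simulate_counts(sim)
        truth.effects.to_csv(os.path.join(outdir, "sim_truth_effects.tsv"),
                             sep="\t", index=False)
        log.info("simulated %d cells x %d genes", adata.n_obs, adata.n_vars)

        # --- QC + normalization -------------------------------------------
        adata = qc_mod.qc_pipeline(
            adata, min_cells=config.min_cells_per_gene,
            min_genes=config.min_genes_per_cell,
            max_genes=config.max_genes_per_cell,
            max_mito_pct=config.max_mito_pct)
        if adata.n_obs == 0 or adata.n_vars == 0:
            raise RuntimeError("QC removed all cells or genes; check thresholds")
        log.info("after QC: %d cells x %d genes", adata.n_obs, adata.n_vars)
        summary["n_cells_qc"] = int(adata.n_obs)
        summary["n_genes_qc"] = int(adata.n_vars)

        # --- per-population DE --------------------------------------------
        populations = sorted(adata.obs["cell_type"].astype(str).unique())
        tables = {}
        for pop in populations:
            tbl = de_table(adata, pop, sex_covariate=config.sex_covariate,
                           lfc_min=config.lfc_min, fdr_max=config.fdr_max,
                           min_cells_detected=config.min_cells_detected)
            tbl.to_csv(os.path.join(outdir, f"de_{pop}.tsv"), sep="\t", index=False)
            tables[pop] = tbl
        summary["de_events"] = summarize_events(list(tables.values()))
        log.info("DE events: %s", summary["de_events"])

        # --- burden ranking -------------------------------------------------
        down, exclusions = vuln_mod.downsample_cells(
            adata, n=config.burden_n_cells, seed=config.burden_seed)
        if down.n_obs:
            qc_mod.compute_cdr(down)
            burden = vuln_mod.deg_burden(
                down, exclusions, lfc_min=config.lfc_min, fdr_max=config.fdr_max,
                min_cells_detected=config.min_cells_detected)
        else:
            burden = pd.DataFrame({"population": exclusions["population"],
                                   "n_deg": 0, "n_cells_used": 0,
                                   "excluded": True,
                                   "reason": exclusions["reason"]})
        burden.to_csv(os.path.join(outdir, "burden.tsv"), sep="\t", index=False)
        ranked = burden[~burden["excluded"]]
        top_pop = str(ranked["population"].iloc[0]) if len(ranked) else None
        summary["burden_top_population"] = top_pop
        summary["vulnerable_population_truth"] = sim.vulnerable_type
        log.info("burden ranking: top=%s", top_pop)

        # --- disease-gene enrichment (relaxed thresholds) -------------------
        gene_sets = io_mod.gene_sets_from_var(adata.var)
        has_homolog = adata.var["has_homolog"]
        enr_rows = []
        for pop, tbl in tables.items():
            relaxed = apply_thresholds(tbl, config.lfc_min_relaxed,
                                       config.fdr_max_relaxed)
            for set_name, genes in sorted(gene_sets.items()):
                for direction in ("down", "up"):
                    try:
                        res = vuln_mod.disease_enrichment(
                            relaxed, genes, direction, has_homolog=has_homolog)
                    except ValueError:
                        continue
                    enr_rows.append({
                        "population": pop, "gene_set": set_name,
                        "direction": direction,
                        "odds_ratio": res["odds_ratio"], "p": res["p"],
                        "n_sig_in_set": res["n_sig_in_set"],
                        "n_universe": res["n_universe"]})
        enrichment = pd.DataFrame(enr_rows)
        enrichment.to_csv(os.path.join(outdir, "enrichment.tsv"),
                          sep="\t", index=False)

        # --- signatures + reversal ------------------------------------------
        sig_pop = top_pop or sim.vulnerable_type
        celltype_tbl = tables[sig_pop]
        pseudo_tbl = rev_mod.pseudo_bulk_de(
            adata, sex_covariate=config.sex_covariate, lfc_min=config.lfc_min,
            fdr_max=config.fdr_max, min_cells_detected=config.min_cells_detected)
        pseudo_tbl.to_csv(os.path.join(outdir, "de_pseudo_bulk.tsv"),
                          sep="\t", index=False)

        query_ct = rev_mod.extract_down_signature(celltype_tbl, k=config.signature_k)
        query_pb = rev_mod.extract_down_signature(pseudo_tbl, k=config.signature_k)
        for name, q in (("celltype", query_ct), ("pseudo_bulk", query_pb)):
            with open(os.path.join(outdir, f"signature_{name}.txt"), "w") as fh:
                fh.write("\n".join(q) + "\n")

        # reference library planted against the vulnerable population's true
        # effect profile, restricted to genes surviving QC
        disease_vec = pd.Series(0.0, index=celltype_tbl["gene"].to_numpy())
        vuln_truth = truth.planted_genes(sim.vulnerable_type)
        for _, row in vuln_truth.iterrows():
            if row["gene"] in disease_vec.index:
                disease_vec.loc[row["gene"]] = row["true_log2fc"]
        z, compound_meta = synthdata.simulate_reference_signatures(sim, disease_vec)
        io_mod.write_signatures(z, compound_meta, os.path.join(outdir, "reference"))

        conn = {}
        for name, q in (("celltype", query_ct), ("pseudo_bulk", query_pb)):
            scores = rev_mod.connectivity_scores(
                q, z, candidate_tau=config.candidate_tau)
            scores.to_csv(os.path.join(outdir, f"connectivity_{name}.tsv"), sep="\t")
            conn[name] = scores
            summary[f"n_candidates_{name}"] = int(scores["candidate"].sum())
        overlap = rev_mod.compare_candidate_lists(
            conn["celltype"], conn["pseudo_bulk"], compound_meta,
            top_k=config.top_k_overlap)
        with open(os.path.join(outdir, "overlap.json"), "w") as fh:
            json.dump(overlap, fh, indent=2, sort_keys=True)
        summary["overlap"] = overlap
        reverser_ids = set(compound_meta.index[compound_meta["role"] == "reverser"])
        bottom = conn["celltype"].sort_values("tau").head(
            max(10, len(reverser_ids))).index
        summary["reversers_recovered_celltype"] = int(
            len(reverser_ids & set(bottom)))
        log.info("reversal: %s", overlap)

        # --- CLIP density ----------------------------------------------------
        gene_annot = synthdata.make_gene_annotation(sim)
        sites = synthdata.simulate_clip_sites(gene_annot, sim)
        io_mod.write_bed(sites, os.path.join(outdir, "clip_sites.bed"))
        profile = clip_mod.density_profile(sites, gene_annot)
        profile.to_csv(os.path.join(outdir, "clip_profile.tsv"), sep="\t")
        enriched = truth.clip_enriched_gene
        summary["clip_enriched_gene_percentile"] = float(
            profile.loc[enriched, "percentile_density"])

        # --- phenotype statistics -------------------------------------------
        phen = synthdata.simulate_phenotypes(sim)
        phen.to_csv(os.path.join(outdir, "phenotypes.csv"), index=False)
        reports = []
        for measure in sorted(phen["measure"].unique()):
            reports.append(pheno_mod.phenotype_report(
                phen, measure, n_perm=config.pheno_n_perm, seed=sim.seed))
        pheno_stats = pd.concat(reports, ignore_index=True)
        pheno_stats.to_csv(os.path.join(outdir, "phenotype_stats.tsv"),
                           sep="\t", index=False)
        summary["pheno_min_permuted_p"] = float(pheno_stats["p_permuted"].min())

        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        log.info("pipeline complete")
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()


def demo_config(seed: int = 0) -> RunConfig:
    """A desk-scale configuration that exercises every stage end to end."""
    from .config import SimConfig
    cfg = RunConfig(sim=SimConfig(seed=seed))
    # synthetic cells detect a few hundred of 1,500 genes; scale the per-cell
    # gene-count gates accordingly (mito gates keep their region defaults)
    cfg.min_genes_per_cell = 100
    cfg.max_genes_per_cell = 5000
    cfg.pheno_n_perm = 2000
    return cfg
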