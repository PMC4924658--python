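"""End-to-end orchestration: simulate -> integrate -> consensus -> network ->
enrichment -> proteomics -> survival, with a run manifest.

The demo scenario wires the synthetic generators together the way the real
study is shaped: a three-study expression cohort with planted differential
expression, an interaction atlas over the same gene universe whose planted
hubs coincide with the shifted proteins of a paired proteomics experiment,
pathway sets with one set enriched for the planted signature, and a survival
table whose high-expression group carries an elevated hazard. Every stage
writes plain-text outputs and records its row/node counts in a JSON manifest;
a rerun with the same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import ExpressionCohort
from .consensus import run_consensus
from .enrichment import enrich, read_gmt, write_gmt
from .exceptions import PipelineStageError
from .integrate import (BatchEffectModel, batch_mean_contrast,
                        merge_on_shared_genes)
from .network import (build_seed_network, clean_network, interactions_from_frame,
                      load_interactions, node_topology, rank_roots, steiner_tree)
from .proteomics import PairedAbundanceTable, filter_significant, paired_t
from .simulate import (SimulationConfig, simulate_multistudy_expression,
                       simulate_paired_proteomics, simulate_pathways,
                       simulate_ppi, simulate_survival)
from .survival import km_curve, logrank_tables, median_split, pearson_correlation


@dataclass
class RunConfig:
    """Flat configuration of a full pipeline run.

    ``seed`` is the master seed; each random stage derives its own seed from
    it, and all seeds are recorded in the manifest.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    # expression simulation / integration
    n_genes: int = 2000
    de_fraction: float = 0.05
    log2_fc: float = 1.5
    batch_shift_sd: float = 1.0
    batch_scale_sd: float = 0.2
    noise_sd: float = 0.5
    # consensus calling
    k: int = 8
    m: int = 6
    mode: str = "mixed"
    fdr: float = 0.05
    fc: float = 1.2
    n_permutations: int = 200
    # interaction network
    n_hubs: int = 17
    attachment: int = 2
    order: int = 1
    # pathways
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 60)
    enriched_fraction: float = 0.8
    # proteomics
    n_proteins: int = 500
    n_pairs: int = 3
    protein_shift: float = 4.0
    protein_noise_sd: float = 0.1
    alpha: float = 0.001
    # survival
    n_patients: int = 200
    hazard_ratio: float = 3.0
    censor_rate: float = 0.2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pathway_size_range" in raw:
            raw["pathway_size_range"] = tuple(raw["pathway_size_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["pathway_size_range"] = list(d["pathway_size_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def stage_seed(self, offset: int) -> int:
        return (self.seed * 7919 + offset) % (2**31 - 1)


def _stage(name):
    """Decorator: re-raise any stage failure with the stage name attached."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a freshly generated synthetic scenario.

    Writes inputs under ``<out_dir>/inputs``, stage outputs under
    ``<out_dir>/results`` and the manifest to ``<out_dir>/manifest.json``.
    Returns the manifest dictionary.
    """
    out = Path(config.out_dir)
    inputs = out / "inputs"
    results = out / "results"
    inputs.mkdir(parents=True, exist_ok=True)
    results.mkdir(parents=True, exist_ok=True)
    params = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    manifest: dict = {"package_version": __version__,
                      "config": json.loads(json.dumps(params)),
                      "stages": {}}

    # -- stage 1: simulate the scenario ---------------------------------
    @_stage("simulate")
    def simulate():
        sim_cfg = SimulationConfig(
            n_genes=config.n_genes, de_fraction=config.de_fraction,
            log2_fc=config.log2_fc, batch_shift_sd=config.batch_shift_sd,
            batch_scale_sd=config.batch_scale_sd, noise_sd=config.noise_sd,
            seed=config.stage_seed(1))
        cohort, truth = simulate_multistudy_expression(sim_cfg)
        rng = np.random.default_rng(config.stage_seed(2))
        hubs = sorted(rng.choice(sorted(truth.de_genes), size=config.n_hubs,
                                 replace=False))
        atlas_edges, net_truth = simulate_ppi(
            n_nodes=cohort.n_genes, n_seed_hubs=config.n_hubs,
            attachment=config.attachment, seed=config.stage_seed(3),
            node_ids=list(cohort.gene_ids), hub_ids=hubs)
        pathways, enriched_name = simulate_pathways(
            list(cohort.gene_ids), n_sets=config.n_pathways,
            set_size_range=config.pathway_size_range,
            enriched_set_fraction_of_signature=config.enriched_fraction,
            seed=config.stage_seed(4), signature=sorted(truth.de_genes))
        prot_ids = hubs + [g for g in cohort.gene_ids if g not in set(hubs)
                           ][:config.n_proteins - config.n_hubs]
        prot_table, prot_truth = simulate_paired_proteomics(
            n_proteins=config.n_proteins, n_pairs=config.n_pairs,
            shifted_proteins=config.n_hubs, shift=config.protein_shift,
            noise_sd=config.protein_noise_sd, seed=config.stage_seed(5),
            protein_ids=prot_ids, shifted_ids=hubs)
        surv = simulate_survival(config.n_patients, config.hazard_ratio,
                                 censor_rate=config.censor_rate,
                                 seed=config.stage_seed(6))
        # persist inputs
        for study_cohort in cohort.split_by_study():
            study_cohort.to_tsv(inputs / f"matrix_{study_cohort.name}.tsv",
                                inputs / f"annotation_{study_cohort.name}.tsv")
        atlas_edges.to_csv(inputs / "atlas.sif", sep="\t", header=False,
                           index=False)
        write_gmt(pathways, inputs / "pathways.gmt")
        prot_table.to_csv(inputs / "proteomics.tsv", sep="\t", index=False)
        surv.to_csv(inputs / "survival.tsv", sep="\t", index=False)
        manifest["stages"]["simulate"] = {
            "n_genes": cohort.n_genes, "n_samples": cohort.n_samples,
            "n_planted_de": len(truth.de_genes),
            "n_atlas_edges": int(len(atlas_edges)),
            "n_pathways": len(pathways), "planted_hubs": hubs,
            "seeds": {f"stage_{i}": config.stage_seed(i) for i in range(1, 7)}}
        return cohort, truth, pathways, enriched_name, prot_table, surv, hubs

    cohort, truth, pathways, enriched_name, prot_table, surv, hubs = simulate()

    # -- stage 2: integrate ---------------------------------------------
    @_stage("integrate")
    def integrate():
        merged = merge_on_shared_genes(cohort.split_by_study())
        contrast_before = batch_mean_contrast(merged)
        fit = BatchEffectModel(merged).fit()
        corrected = fit.corrected()
        contrast_after = batch_mean_contrast(corrected)
        corrected.to_tsv(results / "corrected_matrix.tsv",
                         results / "corrected_annotation.tsv")
        manifest["stages"]["integrate"] = {
            "n_merged_genes": merged.n_genes,
            "n_batches": int(merged.batch.nunique()),
            "batch_contrast_before": round(contrast_before, 6),
            "batch_contrast_after": round(contrast_after, 6)}
        return corrected

    corrected = integrate()

    # -- stage 3: consensus differential expression ----------------------
    @_stage("consensus")
    def consensus():
        table, sam_results, plan = run_consensus(
            corrected, k=config.k, m=config.m, mode=config.mode,
            fdr=config.fdr, fc=config.fc, B=config.n_permutations,
            seed=config.stage_seed(7))
        table.to_csv(results / "signatures.tsv", sep="\t")
        robust = sorted(table.index[table["robust"]])
        true_set = set(truth.de_genes)
        tp = len(set(robust) & true_set)
        manifest["stages"]["consensus"] = {
            "k": config.k, "m": config.m,
            "n_robust": len(robust),
            "sensitivity": round(tp / len(true_set), 4) if true_set else None,
            "precision": round(tp / len(robust), 4) if robust else None,
            "per_dataset_calls": [int(r.table["called"].sum())
                                  for r in sam_results]}
        return robust

    robust = consensus()

    # -- stage 4: proteomics filter --------------------------------------
    @_stage("proteomics")
    def proteomics():
        table = PairedAbundanceTable.from_frame(prot_table)
        res = paired_t(table)
        res.to_csv(results / "prot_diff.tsv", sep="\t")
        sig = filter_significant(res, alpha=config.alpha)
        manifest["stages"]["proteomics"] = {
            "n_proteins": len(res), "n_pairs": table.n_pairs,
            "n_significant": len(sig),
            "patterns": sig["pattern"].value_counts().to_dict()}
        return sorted(sig.index)

    seed_proteins = proteomics()

    # -- stage 5: network -------------------------------------------------
    @_stage("network")
    def network():
        atlas = load_interactions([inputs / "atlas.sif"])
        net = clean_network(build_seed_network(atlas, seed_proteins,
                                               order=config.order))
        net.write_sif(results / "network.sif")
        topo = node_topology(net)
        topo.to_csv(results / "node_attributes.tsv", sep="\t")
        ranking = rank_roots(net)
        ranking.to_csv(results / "root_ranking.tsv", sep="\t")
        roots_in = [r for r in net.roots]
        st = steiner_tree(net, roots_in)
        with open(results / "steiner.sif", "w") as fh:
            for a, b in st.edges:
                fh.write(f"{a}\tpp\t{b}\n")
        top = ranking.index[0] if len(ranking) else None
        manifest["stages"]["network"] = {
            "n_nodes": net.n_nodes, "n_edges": net.n_edges,
            "n_roots": len(net.roots),
            "top_root": top,
            "top_root_degree": int(ranking["k_n"].iloc[0]) if top else None,
            "top_root_cc": float(ranking["cc"].iloc[0]) if top else None,
            "top_root_is_planted_hub": bool(top in set(hubs)) if top else None,
            "steiner_cost": st.cost}
        return net

    network()

    # -- stage 6: enrichment ----------------------------------------------
    @_stage("enrichment")
    def enrichment():
        sets = read_gmt(inputs / "pathways.gmt")
        table = enrich(robust, sets, list(corrected.gene_ids))
        table.to_csv(results / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["enrichment"] = {
            "n_pathways": len(table),
            "top_pathway": table["pathway"].iloc[0] if len(table) else None,
            "top_p_right": float(table["p_right"].iloc[0]) if len(table) else None,
            "planted_pathway_rank": int(
                table.index[table["pathway"] == enriched_name][0]) + 1
            if enriched_name in set(table["pathway"]) else None}

    enrichment()

    # -- stage 7: survival -------------------------------------------------
    @_stage("survival")
    def survival():
        split = median_split(surv)
        high = split[split["group"] == "high"]
        low = split[split["group"] == "low"]
        for name, grp in (("high", high), ("low", low)):
            km_curve(grp["time"], grp["event"]).to_frame().to_csv(
                results / f"km_{name}.tsv", sep="\t", index=False)
        lr = logrank_tables(high, low)
        rng = np.random.default_rng(config.stage_seed(8))
        partner = (0.8 * split["expression"].to_numpy()
                   + rng.normal(0, 0.5, len(split)))
        r, rp = pearson_correlation(split["expression"].to_numpy(), partner)
        pd.DataFrame([{"chi2": lr.chi2, "p": lr.p, "pearson_r": r,
                       "pearson_p": rp}]).to_csv(
            results / "survival_summary.tsv", sep="\t", index=False)
        manifest["stages"]["survival"] = {
            "n_high": len(high), "n_low": len(low),
            "logrank_chi2": round(lr.chi2, 6), "logrank_p": lr.p,
            "pearson_r": round(r, 6)}

    survival()

    config.to_yaml(out / "run_config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
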