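"""End-to-end orchestration of the analysis stages.

Stages run in dependency order (simulate -> diversity -> diffabund -> mlg ->
network -> select -> classify -> metabolite -> preclinical) with flat-file
(TSV/JSON) handoff, so any stage can be inspected or re-run from its
persisted inputs. The run report collects per-stage status, headline
statistics, the output-file manifest, and the seed.
"""

from __future__ import annotations

import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from gutmwas import classify, diffabund, diversity, io, metabolites, mlg, preclinical, sparcc
from gutmwas.simulate import (
    CohortDesign,
    simulate_gene_catalog,
    simulate_metabolites,
    simulate_mouse_experiment,
    simulate_taxon_table,
)

DEFAULT_STAGES = [
    "simulate",
    "diversity",
    "diffabund",
    "mlg",
    "network",
    "select",
    "classify",
    "metabolite",
    "preclinical",
]

DEFAULT_MOUSE_ARMS = [
    # per-arm (label, n, p_aneurysm, p_rupture | aneurysm), the study's
    # printed FMT incidence/rupture rates used as design parameters
    ["UIA-FMT", 20, 0.85, 0.82],
    ["Con-FMT", 20, 0.45, 0.22],
]


def run_pipeline(config: dict) -> dict:
    """Execute the enabled stages and return the machine-readable run report."""
    outdir = Path(config.get("outdir", "gutmwas_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", DEFAULT_STAGES)
    report: dict = {"seed": seed, "stages": {}, "manifest": [], "headline": {}}

    design_cfg = dict(config.get("design", {}))
    design_cfg.setdefault("seed", seed)
    design = CohortDesign(**design_cfg)

    state: dict = {}

    def emit(name: str, path: Path) -> None:
        report["manifest"].append(str(path))

    def stage_done(name: str, t0: float, **stats) -> None:
        report["stages"][name] = {"status": "ok", "seconds": round(time.time() - t0, 3), **stats}

    if "simulate" in stages:
        t0 = time.time()
        catalog, annotations, gene_truth = simulate_gene_catalog(design)
        species_table, taxon_truth = simulate_taxon_table(design, "species")
        panel = simulate_metabolites(design, species_table)
        mouse = simulate_mouse_experiment(
            [tuple(a) for a in config.get("mouse_arms", DEFAULT_MOUSE_ARMS)],
            seed=seed,
        )
        state.update(
            catalog=catalog,
            annotations=annotations,
            gene_truth=gene_truth,
            species=species_table,
            taxon_truth=taxon_truth,
            panel=panel,
            mouse=mouse,
        )
        io.write_catalog(catalog, outdir / "gene_depth.tsv", outdir / "gene_meta.tsv")
        annotations.to_csv(outdir / "gene_annotations.tsv", sep="\t", index=False)
        gene_truth.to_csv(outdir / "truth_clusters.tsv", sep="\t", index=False)
        io.write_table(species_table, outdir / "species_abundance.tsv")
        io.write_metadata(species_table.groups, outdir / "sample_metadata.tsv")
        taxon_truth.to_csv(outdir / "truth_taxa.tsv", sep="\t", index=False)
        io.write_metabolites(panel, outdir / "metabolites.tsv", outdir / "metabolite_meta.tsv")
        mouse.to_csv(outdir / "mouse_outcomes.tsv", sep="\t", index=False)
        for f in (
            "gene_depth.tsv",
            "gene_meta.tsv",
            "gene_annotations.tsv",
            "truth_clusters.tsv",
            "species_abundance.tsv",
            "sample_metadata.tsv",
            "truth_taxa.tsv",
            "metabolites.tsv",
            "metabolite_meta.tsv",
            "mouse_outcomes.tsv",
        ):
            emit("simulate", outdir / f)
        stage_done("simulate", t0, n_genes=design.n_genes, n_samples=design.n_samples)

    if "species" not in state:
        inputs = config.get("inputs", {})
        if "species" not in inputs or "metadata" not in inputs:
            raise ValueError("without the simulate stage, config.inputs needs species + metadata paths")
        state["species"] = io.read_table(inputs["species"], inputs["metadata"])
        if "mouse" in inputs:
            state["mouse"] = pd.read_csv(inputs["mouse"], sep="\t")
        if "metabolites" in inputs and "metabolite_meta" in inputs:
            state["panel"] = io.read_metabolites(inputs["metabolites"], inputs["metabolite_meta"])
        if "gene_depth" in inputs and "gene_meta" in inputs:
            state["catalog"] = io.read_catalog(inputs["gene_depth"], inputs["gene_meta"])
            state["annotations"] = pd.read_csv(inputs["gene_annotations"], sep="\t")
    species_table = state["species"]

    if "diversity" in stages:
        t0 = time.time()
        shannon = species_table.data.apply(lambda col: diversity.shannon_index(col.values))
        bc = diversity.bray_curtis(species_table)
        ord_res = diversity.pcoa(bc)
        ano = diversity.anosim(
            bc, species_table.groups, n_permutations=config.get("anosim_permutations", 999),
            seed=seed,
        )
        bc.to_csv(outdir / "bray_curtis.tsv", sep="\t")
        ord_res.coordinates.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
        emit("diversity", outdir / "bray_curtis.tsv")
        emit("diversity", outdir / "pcoa_coordinates.tsv")
        report["headline"]["shannon_mean"] = float(shannon.mean())
        report["headline"]["anosim_R"] = ano.R
        report["headline"]["anosim_p"] = ano.p
        stage_done("diversity", t0, anosim_R=ano.R, anosim_p=ano.p)

    if "diffabund" in stages:
        t0 = time.time()
        da = diffabund.differential_features(species_table)
        da.to_csv(outdir / "differential_species.tsv", sep="\t", index=False)
        emit("diffabund", outdir / "differential_species.tsv")
        state["da_species"] = da
        truth_taxa = set(state["taxon_truth"]["taxon"]) if "taxon_truth" in state else set()
        recovered = len(truth_taxa & set(da["feature_id"])) / len(truth_taxa) if truth_taxa else None
        report["headline"]["n_differential_species"] = int(len(da))
        if recovered is not None:
            report["headline"]["taxon_recovery"] = recovered
        stage_done("diffabund", t0, n_differential=int(len(da)))

    if "mlg" in stages:
        t0 = time.time()
        catalog = state["catalog"]
        gene_table = pd.DataFrame(
            catalog.depth.values, index=catalog.gene_ids, columns=catalog.depth.columns
        )
        from gutmwas.containers import AbundanceTable

        gene_ab = AbundanceTable(
            data=gene_table / gene_table.sum(axis=0),
            groups=species_table.groups,
            level="gene",
        )
        marker_df = diffabund.differential_features(gene_ab)
        markers = list(marker_df["feature_id"])
        mlgs = mlg.build_mlgs(catalog, markers, state["annotations"])
        mlg_ab = mlg.mlg_table(mlgs)
        mlg_ab.to_csv(outdir / "mlg_abundance.tsv", sep="\t")
        tax = pd.DataFrame(
            [
                {
                    "mlg_id": m.mlg_id,
                    "size": m.size,
                    "taxonomy_level": m.taxonomy_level,
                    "taxonomy_name": m.taxonomy_name,
                }
                for m in mlgs
            ]
        )
        tax.to_csv(outdir / "mlg_taxonomy.tsv", sep="\t", index=False)
        members = pd.DataFrame(
            [(m.mlg_id, g) for m in mlgs for g in m.member_genes],
            columns=["mlg_id", "gene_id"],
        )
        members.to_csv(outdir / "mlg_members.tsv", sep="\t", index=False)
        for f in ("mlg_abundance.tsv", "mlg_taxonomy.tsv", "mlg_members.tsv"):
            emit("mlg", outdir / f)
        state["mlgs"] = mlgs
        state["mlg_abundance"] = mlg_ab
        report["headline"]["n_mlgs"] = len(mlgs)
        stage_done("mlg", t0, n_markers=len(markers), n_mlgs=len(mlgs))

    if "network" in stages and len(state.get("mlgs", [])) >= 4:
        t0 = time.time()
        cfg = sparcc.SparccConfig(
            seed=seed,
            n_dirichlet_draws=config.get("sparcc_draws", 5),
            n_permutations=config.get("sparcc_permutations", 50),
        )
        mlg_ab = state["mlg_abundance"]
        rho = sparcc.sparcc_correlation(mlg_ab, cfg)
        p = sparcc.pseudo_pvalues(mlg_ab, rho.values, cfg)
        edges = sparcc.build_network(rho, p.values)
        edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        sparcc.edge_list_to_graphml(edges, outdir / "network.graphml")
        emit("network", outdir / "network_edges.tsv")
        emit("network", outdir / "network.graphml")
        report["headline"]["n_edges_positive"] = int((edges["sign"] == "positive").sum())
        report["headline"]["n_edges_negative"] = int((edges["sign"] == "negative").sum())
        stage_done("network", t0, n_edges=int(len(edges)))

    if "select" in stages:
        t0 = time.time()
        from gutmwas.stability import McConfig, cutoff_scan, mc_stability

        X = species_table.data.T
        y = species_table.groups.values
        cfg = McConfig(seed=seed, cap=config.get("stability_cap", 500))
        res = cutoff_scan(mc_stability(X, y, cfg), X, y, cfg)
        pd.DataFrame(
            {"feature_id": res.feature_ids, "c": res.c, "beta_mean": res.beta_mean,
             "beta_sd": res.beta_sd}
        ).to_csv(outdir / "stability_c.tsv", sep="\t", index=False)
        pd.DataFrame(res.accuracy_by_cutoff, columns=["cutoff", "cv_accuracy"]).to_csv(
            outdir / "stability_curve.tsv", sep="\t", index=False
        )
        pd.Series(sorted(res.selected), name="feature_id").to_csv(
            outdir / "stability_selected.tsv", sep="\t", index=False
        )
        for f in ("stability_c.tsv", "stability_curve.tsv", "stability_selected.tsv"):
            emit("select", outdir / f)
        report["headline"]["n_selected_features"] = len(res.selected)
        stage_done("select", t0, n_selected=len(res.selected))

    if "classify" in stages:
        t0 = time.time()
        ev = classify.evaluate_classifier(
            species_table,
            species_table.groups.values,
            n_trials=config.get("classify_trials", 10),
            n_boot=config.get("classify_boot", 200),
            seed=seed,
        )
        pd.DataFrame(ev.roc_points, columns=["fpr", "tpr"]).to_csv(
            outdir / "roc_points.tsv", sep="\t", index=False
        )
        io.write_json(
            {"auc": ev.auc, "ci": list(ev.ci), "mean_accuracy": ev.mean_accuracy},
            outdir / "classifier_eval.json",
        )
        emit("classify", outdir / "roc_points.tsv")
        emit("classify", outdir / "classifier_eval.json")
        report["headline"]["auc"] = ev.auc
        report["headline"]["auc_ci"] = list(ev.ci)
        stage_done("classify", t0, auc=ev.auc)

    if "metabolite" in stages:
        t0 = time.time()
        heat = metabolites.correlation_heatmap(species_table, state["panel"])
        heat.to_long().to_csv(outdir / "species_metabolite_correlations.tsv", sep="\t", index=False)
        emit("metabolite", outdir / "species_metabolite_correlations.tsv")
        shown = int(heat.mask.values.sum())
        report["headline"]["n_correlations_shown"] = shown
        stage_done("metabolite", t0, n_shown=shown)

    if "preclinical" in stages:
        t0 = time.time()
        mouse = state["mouse"]
        arms = list(pd.unique(mouse["arm"]))
        inc = (
            pd.crosstab(mouse["arm"], mouse["aneurysm"])
            .reindex(index=arms, columns=[True, False], fill_value=0)
        )
        fisher_inc = preclinical.fisher_exact_2x2(inc.values)
        an_pos = mouse[mouse["aneurysm"]]
        rup = (
            pd.crosstab(an_pos["arm"], an_pos["rupture"])
            .reindex(index=arms, columns=[True, False], fill_value=0)
        )
        fisher_rup = preclinical.fisher_exact_2x2(rup.values)
        lr = preclinical.logrank_test(mouse, arms)
        curves = {}
        for arm in arms:
            c = preclinical.km_curve(mouse, arm)
            curves[arm] = {
                "times": c.times,
                "at_risk": c.at_risk,
                "survival": c.survival,
            }
            pd.DataFrame(
                {"time": c.times, "at_risk": c.at_risk, "survival": c.survival}
            ).to_csv(outdir / f"km_{arm}.tsv", sep="\t", index=False)
            emit("preclinical", outdir / f"km_{arm}.tsv")
        tests = {
            "fisher_incidence_p": fisher_inc.p,
            "fisher_rupture_p": fisher_rup.p,
            "logrank_p": lr.p,
        }
        io.write_json(tests, outdir / "preclinical_tests.json")
        emit("preclinical", outdir / "preclinical_tests.json")
        report["headline"].update(tests)
        stage_done("preclinical", t0, **tests)

    io.write_json(report, outdir / "run_report.json")
    return report
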