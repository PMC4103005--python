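"""End-to-end orchestration of the phenotype-profiling analysis.

Stages (each optional, each writing its outputs under one directory):
simulate -> extract image traits -> randomization tests -> correlations ->
clustering -> PCA -> expression co-clustering. A single master seed feeds
per-stage substreams (spawned up front in a fixed order, so toggling one
stage never shifts another stage's draws), and the final ``RunReport`` JSON
records every parameter and summary statistic needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import DEVELOPMENT_TRAITS, TraitTable
from .correlation import correlation_report
from .expression import (
    average_linkage_cluster,
    cocluster_enrichment,
    normalize_expression,
)
from .images import segment_aggregates, summarize_image_traits
from .multivariate import (
    linkage_to_newick,
    pca,
    trait_group_report,
    ward_cluster,
    zscore,
)
from .stats import call_mutants, pleiotropy_summary
from .synthetic import (
    GroundTruth,
    SimulationConfig,
    random_image_spec,
    simulate_development_image,
    simulate_expression_matrix,
    simulate_trait_table,
)

__all__ = ["PipelineConfig", "run_pipeline", "read_trait_table"]

_STAGES = ("simulate", "images", "expression", "test", "correlate",
           "cluster", "pca", "cocluster")


@dataclass
class PipelineConfig:
    """Everything a full run needs; JSON-serializable."""

    out_dir: str = "myxphen_run"
    rng_seed: int = 0
    # stage toggles
    with_images: bool = True
    with_expression: bool = True
    # inputs: simulate by default, or load a provided trait table
    trait_table_path: str | None = None
    expression_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # analysis parameters
    alpha: float = 0.05
    n_iterations: int = 1000
    fdr_family: str = "trait"
    k_strains: int = 4
    k_traits: int = 2
    k_expression: int = 4
    k_phenotype_dev: int = 4
    n_images: int = 6
    image_noise_sd: float = 3.0
    heatmap: bool = False

    def validate(self) -> None:
        if self.fdr_family not in ("trait", "all"):
            raise ValueError("fdr_family must be 'trait' or 'all'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for path in (self.trait_table_path, self.expression_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input not found: {path}")
        self.simulation.validate()


def read_trait_table(path, wildtype: str | None = None) -> TraitTable:
    """Load and validate a tidy TSV trait table."""
    kwargs = {} if wildtype is None else {"wildtype": wildtype}
    return TraitTable.from_tsv(path, **kwargs)


def _stage_seeds(master: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(master).spawn(len(_STAGES))
    return dict(zip(_STAGES, children))


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the RunReport dict.

    A stage failure aborts the run with the stage name and cause; outputs
    written so far stay on disk next to a ``FAILED`` marker file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.rng_seed)
    report: dict = {
        "version": __version__,
        "seed": config.rng_seed,
        "stages": {},
    }
    current = "setup"
    try:
        # ------------------------------------------------------ simulate
        current = "simulate"
        if config.trait_table_path:
            table = read_trait_table(config.trait_table_path)
            truth = None
            params = {"source": config.trait_table_path}
        else:
            sim = dataclasses.replace(
                config.simulation, rng_seed=_seed_int(seeds["simulate"]))
            table, truth = simulate_trait_table(sim)
            truth.to_json(out / "ground_truth.json")
            params = {"source": "synthetic",
                      "n_strains": sim.n_strains,
                      "effect_fraction": sim.effect_fraction,
                      "effect_size_sd": sim.effect_size_sd,
                      "group_separation_sd": sim.group_separation_sd}
        table.to_tsv(out / "trait_table.tsv")
        report["stages"]["simulate"] = {
            "status": "ok", "params": params,
            "summary": {"n_strains": len(table.strains),
                        "n_traits": len(table.traits)}}

        # ------------------------------------------------------ images
        if config.with_images:
            current = "images"
            rng = np.random.default_rng(seeds["images"])
            n_exact = 0
            summaries = []
            for i in range(config.n_images):
                spec = random_image_spec(rng, noise_sd=config.image_noise_sd)
                img, img_truth = simulate_development_image(spec)
                agg = segment_aggregates(img, image_id=f"img_{i:03d}")
                interior = [r for r in img_truth.records
                            if not r.touches_edge and r.area >= 200]
                n_exact += int(agg.count == len(interior))
                summaries.append({"image": f"img_{i:03d}",
                                  **summarize_image_traits(agg)})
            pd.DataFrame(summaries).to_csv(
                out / "image_trait_summaries.tsv", sep="\t", index=False)
            report["stages"]["images"] = {
                "status": "ok",
                "params": {"n_images": config.n_images,
                           "noise_sd": config.image_noise_sd},
                "summary": {"count_recovery_rate": n_exact / config.n_images}}
        else:
            report["stages"]["images"] = {"status": "skipped"}

        # ------------------------------------------------------ tests
        current = "test"
        results = call_mutants(
            table, alpha=config.alpha, n_iterations=config.n_iterations,
            rng_seed=_seed_int(seeds["test"]), family=config.fdr_family)
        results.to_csv(out / "test_results.tsv", sep="\t", index=False)
        per_strain, fractions = pleiotropy_summary(results)
        per_strain.to_csv(out / "pleiotropy_per_strain.tsv", sep="\t",
                          index=False)
        per_trait = (results.groupby("trait")["significant"].sum()
                     .astype(int).to_dict())
        report["stages"]["test"] = {
            "status": "ok",
            "params": {"alpha": config.alpha,
                       "n_iterations": config.n_iterations,
                       "family": config.fdr_family},
            "summary": {"significant_per_trait": per_trait, **fractions}}

        # ------------------------------------------------------ correlations
        current = "correlate"
        corr = correlation_report(table)
        corr["zero_order_rho"].to_csv(out / "spearman_zero_order.tsv", sep="\t")
        corr["zero_order_p"].to_csv(out / "spearman_zero_order_p.tsv", sep="\t")
        corr["partial_rho"].to_csv(out / "spearman_partial.tsv", sep="\t")
        corr["partial_p"].to_csv(out / "spearman_partial_p.tsv", sep="\t")
        zo, pa = corr["zero_order_rho"], corr["partial_rho"]
        off = ~np.eye(len(zo), dtype=bool)
        report["stages"]["correlate"] = {
            "status": "ok", "params": {"n_variables": len(zo)},
            "summary": {
                "n_strains_listwise": corr["n_listwise"],
                "mean_abs_zero_order": float(np.nanmean(np.abs(zo.to_numpy()[off]))),
                "mean_abs_partial": float(np.nanmean(np.abs(pa.to_numpy()[off]))),
            }}

        # ------------------------------------------------------ clustering
        current = "cluster"
        summary_matrix = table.summary_matrix(include_wildtype=True)
        z = zscore(summary_matrix)
        strain_cl = ward_cluster(z, axis="strains", k=config.k_strains)
        trait_cl = ward_cluster(z, axis="traits", k=config.k_traits)
        strain_cl.labels.rename_axis("strain").to_frame().to_csv(
            out / "strain_groups.tsv", sep="\t")
        trait_cl.labels.rename_axis("trait").to_frame().to_csv(
            out / "trait_groups.tsv", sep="\t")
        (out / "strain_dendrogram.nwk").write_text(
            linkage_to_newick(strain_cl.linkage, list(z.values.index)))
        (out / "trait_dendrogram.nwk").write_text(
            linkage_to_newick(trait_cl.linkage, list(z.values.columns)))
        if config.heatmap:
            from .multivariate import cluster_heatmap
            cluster_heatmap(z, strain_cl, trait_cl, out / "heatmap.png")
        t_report = trait_group_report(trait_cl, z.values)
        report["stages"]["cluster"] = {
            "status": "ok",
            "params": {"k_strains": config.k_strains,
                       "k_traits": config.k_traits},
            "summary": {
                "strain_group_sizes": strain_cl.group_sizes().to_dict(),
                "trait_groups": t_report["groups"],
            }}

        # ------------------------------------------------------ PCA
        current = "pca"
        p = pca(z)
        p.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
        p.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        pd.Series(p.variance_explained,
                  index=p.loadings.columns, name="variance_pct").to_csv(
            out / "pca_variance.tsv", sep="\t")
        report["stages"]["pca"] = {
            "status": "ok", "params": {},
            "summary": {"variance_explained_pct":
                        [round(float(v), 4) for v in p.variance_explained],
                        "pc1_pc2_pct": float(p.variance_explained[:2].sum())}}

        # ------------------------------------------------------ co-clustering
        if config.with_expression:
            current = "cocluster"
            if config.expression_path:
                expr = pd.read_csv(config.expression_path, sep="\t",
                                   index_col=0)
                expr_truth = None
            else:
                expr, expr_truth = simulate_expression_matrix(
                    n_genes=len(table.mutants),
                    gene_ids=table.mutants,
                    rng_seed=_seed_int(seeds["expression"]))
                expr.to_csv(out / "expression_matrix.tsv", sep="\t")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                norm = normalize_expression(expr)
            expr_cl = average_linkage_cluster(norm, k=config.k_expression)
            expr_cl.labels.rename_axis("gene").to_frame().to_csv(
                out / "expression_clusters.tsv", sep="\t")
            dev = summary_matrix.loc[:, list(DEVELOPMENT_TRAITS)]
            dev_cl = ward_cluster(zscore(dev), axis="strains",
                                  k=config.k_phenotype_dev)
            dev_labels = dev_cl.labels.drop(index=table.wildtype,
                                            errors="ignore")
            cc = cocluster_enrichment(expr_cl.labels, dev_labels)
            cc.counts.to_csv(out / "cocluster_counts.tsv", sep="\t")
            cc.p_adjusted.to_csv(out / "cocluster_p_adjusted.tsv", sep="\t")
            cc.fractions.to_csv(out / "cocluster_fractions.tsv", sep="\t")
            report["stages"]["cocluster"] = {
                "status": "ok",
                "params": {"k_expression": config.k_expression,
                           "k_phenotype_dev": config.k_phenotype_dev},
                "summary": {
                    "n_items": cc.n_items,
                    "min_adjusted_p": float(cc.p_adjusted.to_numpy().min()),
                }}
        else:
            report["stages"]["cocluster"] = {"status": "skipped"}

    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {current}\ncause: {exc!r}\n")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
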