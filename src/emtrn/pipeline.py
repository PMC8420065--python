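"""End-to-end orchestration of the inference chain.

``run_in_memory`` executes the whole chain on a loaded study; the
``stage_*`` functions are file-driven equivalents that each read the
previous stage's outputs from a working directory, so the chain can be
resumed or run piecewise (these back the CLI subcommands).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .bicliques import BicliqueModule, enumerate_maximal_bicliques, modules_table
from .cerna import (
    assemble_emtrn,
    coexpression_screen,
    intersect_with_dmer_targets,
    network_edge_table,
    network_node_table,
    shared_mirna_significance,
)
from .config import StudyConfig
from .downstream import build_drug_network
from .errors import IntegrityError
from .linking import (
    candidate_pairs_by_distance,
    identify_promoter_regulated_genes,
    screen_pairs_by_correlation,
    split_pairs_by_gene_type,
)
from .methylome import (
    EnhancerRegion,
    MethylationMatrix,
    build_enhancer_regions,
    call_dmers,
    call_dpmgs,
    filter_probes_by_missingness,
    fit_group_difference,
    knn_impute,
    map_promoter_probes,
    summarize_promoter_methylation,
    summarize_region_methylation,
)
from .simulate import SyntheticStudy, simulate_study, write_study
from .survival import RiskModel, risk_models_table, screen_prognostic_modules


@dataclass
class PipelineResult:
    regions: list[EnhancerRegion]
    region_meth: MethylationMatrix
    promoter_meth: MethylationMatrix
    dmer_results: pd.DataFrame
    dpmg_results: pd.DataFrame
    promoter_regulated: set[str]
    dmer_lnc_pairs: pd.DataFrame
    dmer_mrna_pairs: pd.DataFrame
    cerna_pairs: pd.DataFrame
    emtrn_edges: pd.DataFrame
    networks: dict
    modules: list[BicliqueModule] = field(default_factory=list)
    risk_models: list[RiskModel] = field(default_factory=list)
    drug_edges: pd.DataFrame | None = None

    @property
    def dmers(self) -> pd.DataFrame:
        return self.dmer_results.loc[self.dmer_results["direction"] != "ns"]

    @property
    def retained_modules(self) -> list[RiskModel]:
        return [m for m in self.risk_models if m.retained]


def run_in_memory(study: SyntheticStudy, config: StudyConfig) -> PipelineResult:
    """Run the full chain on an in-memory study."""
    # --- methylome: QC, imputation, regions, promoters -------------------
    filtered, _removed = filter_probes_by_missingness(study.beta, config.max_missing_fraction)
    complete = knn_impute(filtered, config.knn_k)
    manifest = study.manifest.loc[study.manifest["probe_id"].isin(complete.values.index)]
    regions = build_enhancer_regions(manifest, config.window_half_width)
    region_meth = summarize_region_methylation(complete, regions)
    mapping = map_promoter_probes(manifest, study.genes, config.promoter_length)
    promoter_meth = summarize_promoter_methylation(complete, mapping)

    # --- differential calling --------------------------------------------
    dmer_results = call_dmers(
        fit_group_difference(region_meth), config.dmer_lfc, config.dmer_adj_p
    )
    dpmg_results = call_dpmgs(
        fit_group_difference(promoter_meth), config.dpmg_delta, config.dpmg_adj_p
    )

    # --- DMER -> target gene linking --------------------------------------
    expression = pd.concat([study.lnc_expr, study.mrna_expr])
    promoter_regulated = identify_promoter_regulated_genes(
        promoter_meth, expression, dpmg_results, config.link_p
    )
    dmers = [r for r in regions if dmer_results.loc[r.region_id, "direction"] != "ns"]
    directions = dmer_results.loc[dmer_results["direction"] != "ns", "direction"]
    candidates = candidate_pairs_by_distance(
        dmers, directions, study.genes, promoter_regulated,
        config.max_enhancer_gene_distance,
    )
    pairs = screen_pairs_by_correlation(candidates, region_meth, expression, config.link_p)
    dmer_lnc_pairs, dmer_mrna_pairs = split_pairs_by_gene_type(pairs)

    # --- ceRNA network -----------------------------------------------------
    cerna = shared_mirna_significance(
        study.lnc_mirna, study.mirna_mrna, config.cerna_min_shared,
        config.cerna_fdr, config.mirna_universe,
    )
    cerna = intersect_with_dmer_targets(cerna, dmer_lnc_pairs, dmer_mrna_pairs)
    edges = coexpression_screen(
        cerna, study.lnc_expr, study.mrna_expr, config.coexpr_pcc, config.coexpr_p
    )
    networks = assemble_emtrn(edges, dmer_lnc_pairs, dmer_mrna_pairs, config.hub_fraction)

    # --- modules + survival ------------------------------------------------
    hypo_edges = network_edge_table(networks["hypo"])
    modules = enumerate_maximal_bicliques(
        hypo_edges[["lncrna", "mrna"]],
        config.biclique_min_lncrna, config.biclique_min_mrna,
    )
    risk_models = screen_prognostic_modules(
        modules, study.lnc_expr, study.mrna_expr, study.survival,
        config.seed, config.survival_p, config.standardize_cox,
    )

    # --- drugs --------------------------------------------------------------
    drug_edges, _g = build_drug_network(study.drugs, networks["hypo"])

    return PipelineResult(
        regions=regions,
        region_meth=region_meth,
        promoter_meth=promoter_meth,
        dmer_results=dmer_results,
        dpmg_results=dpmg_results,
        promoter_regulated=promoter_regulated,
        dmer_lnc_pairs=dmer_lnc_pairs,
        dmer_mrna_pairs=dmer_mrna_pairs,
        cerna_pairs=cerna,
        emtrn_edges=edges,
        networks=networks,
        modules=modules,
        risk_models=risk_models,
        drug_edges=drug_edges,
    )


# ---------------------------------------------------------------------------
# file-driven stages
# ---------------------------------------------------------------------------

def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"region_id": str, "gene_id": str})


def _load_regions(outdir: Path) -> list[EnhancerRegion]:
    bed = pd.read_csv(
        outdir / "regions.bed", sep="\t",
        names=["chrom", "start", "end", "region_id"],
    )
    members = pd.read_csv(outdir / "region_probes.tsv", sep="\t")
    by_region = members.groupby("region_id")["probe_id"].agg(list)
    return [
        EnhancerRegion(r.region_id, r.chrom, int(r.start), int(r.end),
                       sorted(by_region.get(r.region_id, [])))
        for r in bed.itertuples()
    ]


def _load_methylation(path: Path, groups_path: Path) -> MethylationMatrix:
    return MethylationMatrix(io.read_matrix(path), io.read_sample_groups(groups_path))


def stage_simulate(config: StudyConfig, outdir: str | Path) -> SyntheticStudy:
    study = simulate_study(config, config.seed)
    write_study(study, outdir)
    return study


def stage_regions(config: StudyConfig, outdir: str | Path) -> None:
    """QC + imputation + region construction + region/promoter summarization."""
    outdir = Path(outdir)
    beta = _load_methylation(outdir / "beta.tsv", outdir / "sample_groups.tsv")
    manifest = io.read_probe_manifest(outdir / "probes.tsv")
    genes = io.read_gene_models(outdir / "genes.tsv")
    filtered, removed = filter_probes_by_missingness(beta, config.max_missing_fraction)
    pd.Series(removed, name="probe_id").to_csv(
        outdir / "removed_probes.tsv", sep="\t", index=False
    )
    complete = knn_impute(filtered, config.knn_k)
    manifest = manifest.loc[manifest["probe_id"].isin(complete.values.index)]
    regions = build_enhancer_regions(manifest, config.window_half_width)
    io.write_regions_bed(regions, outdir / "regions.bed")
    pd.DataFrame(
        [(r.region_id, p) for r in regions for p in r.probes],
        columns=["region_id", "probe_id"],
    ).to_csv(outdir / "region_probes.tsv", sep="\t", index=False)
    region_meth = summarize_region_methylation(complete, regions)
    io.write_matrix(region_meth.values, outdir / "region_beta.tsv")
    mapping = map_promoter_probes(manifest, genes, config.promoter_length)
    promoter_meth = summarize_promoter_methylation(complete, mapping)
    io.write_matrix(promoter_meth.values, outdir / "promoter_beta.tsv")


def stage_dmer(config: StudyConfig, outdir: str | Path) -> None:
    """Moderated differential testing of regions and promoter genes."""
    outdir = Path(outdir)
    region_meth = _load_methylation(outdir / "region_beta.tsv", outdir / "sample_groups.tsv")
    promoter_meth = _load_methylation(outdir / "promoter_beta.tsv", outdir / "sample_groups.tsv")
    dmer = call_dmers(fit_group_difference(region_meth), config.dmer_lfc, config.dmer_adj_p)
    dmer.rename_axis("region_id").to_csv(outdir / "dmer_results.tsv", sep="\t")
    dpmg = call_dpmgs(fit_group_difference(promoter_meth), config.dpmg_delta, config.dpmg_adj_p)
    dpmg.rename_axis("gene_id").to_csv(outdir / "dpmg_results.tsv", sep="\t")


def stage_link(config: StudyConfig, outdir: str | Path) -> None:
    """Promoter-regulated gene exclusion + DMER-gene candidate screening."""
    outdir = Path(outdir)
    genes = io.read_gene_models(outdir / "genes.tsv")
    region_meth = _load_methylation(outdir / "region_beta.tsv", outdir / "sample_groups.tsv")
    promoter_meth = _load_methylation(outdir / "promoter_beta.tsv", outdir / "sample_groups.tsv")
    dmer = _read_table(outdir / "dmer_results.tsv").set_index("region_id")
    dpmg = _read_table(outdir / "dpmg_results.tsv").set_index("gene_id")
    expression = pd.concat(
        [io.read_matrix(outdir / "expr_lncrna.tsv"), io.read_matrix(outdir / "expr_mrna.tsv")]
    )
    excluded = identify_promoter_regulated_genes(promoter_meth, expression, dpmg, config.link_p)
    pd.Series(sorted(excluded), name="gene_id").to_csv(
        outdir / "promoter_regulated_genes.tsv", sep="\t", index=False
    )
    regions = _load_regions(outdir)
    dmers = [r for r in regions if dmer.loc[r.region_id, "direction"] != "ns"]
    directions = dmer.loc[dmer["direction"] != "ns", "direction"]
    candidates = candidate_pairs_by_distance(
        dmers, directions, genes, excluded, config.max_enhancer_gene_distance
    )
    pairs = screen_pairs_by_correlation(candidates, region_meth, expression, config.link_p)
    lnc, mrna = split_pairs_by_gene_type(pairs)
    io.write_edge_list(lnc, outdir / "dmer_lncRNA_pairs.tsv")
    io.write_edge_list(mrna, outdir / "dmer_mRNA_pairs.tsv")


def stage_network(config: StudyConfig, outdir: str | Path) -> None:
    """ceRNA screen + co-expression + EMTRN assembly and export."""
    outdir = Path(outdir)
    lnc_mirna = io.read_edge_list(outdir / "lnc_mirna.tsv", ["lncrna", "mirna"])
    mirna_mrna = io.read_edge_list(outdir / "mirna_mrna.tsv", ["mirna", "mrna"])
    dmer_lnc = _read_table(outdir / "dmer_lncRNA_pairs.tsv")
    dmer_mrna = _read_table(outdir / "dmer_mRNA_pairs.tsv")
    lnc_expr = io.read_matrix(outdir / "expr_lncrna.tsv")
    mrna_expr = io.read_matrix(outdir / "expr_mrna.tsv")
    cerna = shared_mirna_significance(
        lnc_mirna, mirna_mrna, config.cerna_min_shared, config.cerna_fdr,
        config.mirna_universe,
    )
    cerna = intersect_with_dmer_targets(cerna, dmer_lnc, dmer_mrna)
    edges = coexpression_screen(cerna, lnc_expr, mrna_expr, config.coexpr_pcc, config.coexpr_p)
    networks = assemble_emtrn(edges, dmer_lnc, dmer_mrna, config.hub_fraction)
    io.write_graphml(networks["full"], outdir / "emtrn_full.graphml")
    for key in ("hyper", "hypo"):
        io.write_graphml(networks[key], outdir / f"emtrn_{key}.graphml")
        io.write_edge_list(network_edge_table(networks[key]), outdir / f"emtrn_{key}.tsv")
    io.write_edge_list(network_node_table(networks["full"]), outdir / "emtrn_nodes.tsv")


def stage_modules(config: StudyConfig, outdir: str | Path) -> None:
    """Maximal biclique enumeration of the hypomethylation subnetwork."""
    outdir = Path(outdir)
    hypo = _read_table(outdir / "emtrn_hypo.tsv")
    modules = enumerate_maximal_bicliques(
        hypo[["lncrna", "mrna"]] if not hypo.empty else hypo,
        config.biclique_min_lncrna, config.biclique_min_mrna,
    )
    modules_table(modules).to_csv(outdir / "modules.tsv", sep="\t", index=False)


def _load_modules(outdir: Path) -> list[BicliqueModule]:
    table = pd.read_csv(outdir / "modules.tsv", sep="\t")
    return [
        BicliqueModule(r.module_id, frozenset(str(r.lncrnas).split(",")),
                       frozenset(str(r.mrnas).split(",")))
        for r in table.itertuples()
    ]


def stage_survival(config: StudyConfig, outdir: str | Path) -> None:
    """Cox risk-score + train/test log-rank screen of every module."""
    outdir = Path(outdir)
    modules = _load_modules(outdir)
    lnc_expr = io.read_matrix(outdir / "expr_lncrna.tsv")
    mrna_expr = io.read_matrix(outdir / "expr_mrna.tsv")
    survival = io.read_survival(outdir / "survival.tsv")
    models = screen_prognostic_modules(
        modules, lnc_expr, mrna_expr, survival, config.seed,
        config.survival_p, config.standardize_cox,
    )
    risk_models_table(models).to_csv(outdir / "module_survival.tsv", sep="\t", index=False)


def stage_drugs(config: StudyConfig, outdir: str | Path) -> None:
    """Drug--lncRNA bipartite network restricted to the hypo network."""
    outdir = Path(outdir)
    drugs = io.read_edge_list(outdir / "drugs.tsv", ["drug", "lncrna", "direction"])
    hypo = io.read_graphml(outdir / "emtrn_hypo.graphml")
    edges, g = build_drug_network(drugs, hypo)
    io.write_edge_list(edges, outdir / "drug_network.tsv")
    io.write_graphml(g, outdir / "drug_network.graphml")


STAGES = ("regions", "dmer", "link", "network", "modules", "survival", "drugs")


def run_all(config: StudyConfig, outdir: str | Path) -> None:
    """Run every stage in order against an input/working directory."""
    outdir = Path(outdir)
    required = ["probes.tsv", "beta.tsv", "sample_groups.tsv", "genes.tsv"]
    missing = [f for f in required if not (outdir / f).exists()]
    if missing:
        raise IntegrityError(f"missing input files in {outdir}: {missing}")
    for stage in STAGES:
        globals()[f"stage_{stage}"](config, outdir)
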