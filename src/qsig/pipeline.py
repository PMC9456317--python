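"""End-to-end orchestration of the dual-route signature analysis.

One configuration drives: per-tissue log-CPM -> unsupervised PCA route
(discriminant component + gene-score selection) and supervised
moderated-logFC route (top/bottom ranking) -> route-consistency overlap;
across tissues -> shared up/down cores, category counts, preranked GSEA
and shared enriched pathways; on the planted module -> condition-specific
co-expression networks at both thresholds with centralities, giant
components, class partition, rewiring and range-restriction reports.

All randomness flows from one master seed expanded per stage, so two
runs of the same configuration produce identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from qsig import diffexp, gsea, network, overlap, pca
from qsig.io import ExpressionMatrix, GeneSetCollection, log_cpm
from qsig.simulate import SimConfig, SimTruth, generate_experiment

logger = logging.getLogger(__name__)

_STAGE_SEEDS = {"overlap": 11, "gsea": 23, "network": 37}


@dataclass
class PipelineConfig:
    simulate: SimConfig = field(default_factory=SimConfig)
    n_rank: int | None = None        # top/bottom list size; None -> n_genes // 4
    score_threshold: float = 3.0     # |z| cutoff on gene scores
    alpha: float = 0.05              # nominal p for cross-tissue membership
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    r_threshold: float = 0.7
    r_threshold_core: float = 0.98
    overlap_n_perm: int = 0          # >0 adds permutation p to overlap stats
    seed: int = 0                    # master seed for downstream stages
    do_gsea: bool = True
    do_network: bool = True
    outdir: str | None = None

    def validate(self) -> None:
        for t in (self.r_threshold, self.r_threshold_core):
            if not 0.0 < t <= 1.0:
                raise ValueError(f"network threshold {t} outside (0, 1]")
        if self.n_rank is not None and self.n_rank < 1:
            raise ValueError("n_rank must be >= 1")

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1009 + _STAGE_SEEDS[stage]) % (2**31 - 1)


@dataclass
class TissueReport:
    variance_table: pd.DataFrame
    loadings: pd.DataFrame
    discriminant: pca.DiscriminantReport
    de_table: pd.DataFrame
    up: diffexp.RankedGeneList
    down: diffexp.RankedGeneList
    pca_up: list[str]
    pca_down: list[str]
    route_overlap_up: overlap.OverlapResult | None
    route_overlap_down: overlap.OverlapResult | None
    ranking: pd.Series
    pca_result: pca.PCAResult | None = None


@dataclass
class ReportBundle:
    config: PipelineConfig
    tissues: dict[str, TissueReport]
    shared_up: set[str]
    shared_down: set[str]
    cross_overlap: dict[str, overlap.OverlapResult]
    discordant: set[str]
    category_counts: pd.DataFrame | None
    gsea_results: dict[str, list[gsea.EnrichmentStat]]
    shared_pathways: tuple[set[str], set[str], dict] | None
    network_report: dict | None
    truth: SimTruth | None
    manifest: dict


def _config_hash(config: PipelineConfig) -> str:
    """Hash of the analysis-relevant configuration (output location excluded)."""
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)
    payload = {k: v for k, v in config.__dict__.items() if k != "outdir"}
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def analyze_tissue(counts: ExpressionMatrix, design: pd.DataFrame,
                   config: PipelineConfig, tissue: str) -> TissueReport:
    """Run both discovery routes on one tissue and score their agreement."""
    logm = log_cpm(counts)
    n = config.n_rank
    if n is None:
        n = counts.n_genes // 4 if counts.n_genes < 12000 else 6000
    res = pca.sample_correlation_pca(logm)
    vt = pca.variance_table_frame(pca.variance_table(res.eigenvalues))
    disc = pca.find_discriminating_component(res.eigenvectors, design)
    pca_up: list[str] = []
    pca_down: list[str] = []
    if disc.matched:
        s_up, s_down = pca.select_genes_by_score(
            res, disc.component, disc.orientation, mode="top_bottom", n=n)
        pca_up, pca_down = s_up.index.tolist(), s_down.index.tolist()
    records = diffexp.fit_two_group_trend(logm, design)
    up, down = diffexp.rank_top_bottom(records, n=n)
    ranking = diffexp.full_ranking(records)
    ov_up = ov_down = None
    if disc.matched:
        universe = ranking.index
        seed = config.stage_seed("overlap")
        ov_up = overlap.pairwise_overlap(up.genes, pca_up, universe,
                                         n_perm=config.overlap_n_perm, seed=seed)
        ov_down = overlap.pairwise_overlap(down.genes, pca_down, universe,
                                           n_perm=config.overlap_n_perm, seed=seed + 1)
    return TissueReport(
        variance_table=vt, loadings=res.eigenvectors, discriminant=disc,
        de_table=diffexp.records_frame(records), up=up, down=down,
        pca_up=pca_up, pca_down=pca_down,
        route_overlap_up=ov_up, route_overlap_down=ov_down, ranking=ranking,
        pca_result=res)


def run_all(config: PipelineConfig,
            counts: dict[str, ExpressionMatrix] | None = None,
            designs: dict[str, pd.DataFrame] | None = None,
            gene_sets: GeneSetCollection | None = None,
            truth: SimTruth | None = None) -> ReportBundle:
    """Execute the full analysis; simulate inputs unless they are given."""
    config.validate()
    t0 = time.time()
    if counts is None:
        counts, designs, truth, gene_sets = generate_experiment(config.simulate)
        logger.info("simulated %d tissues in %.1fs", len(counts), time.time() - t0)
    assert designs is not None

    tissues: dict[str, TissueReport] = {}
    for name in counts:
        ts = time.time()
        tissues[name] = analyze_tissue(counts[name], designs[name], config, name)
        logger.info("tissue %s analyzed in %.1fs (discriminant=%s)", name,
                    time.time() - ts, tissues[name].discriminant.component)

    names = list(tissues)
    a, b = names[0], names[1] if len(names) > 1 else names[0]
    # cross-tissue membership uses the nominal-p filter within the top/bottom
    # blocks, on the universe of genes measured (post-dedup) in both tissues
    universe = set(tissues[a].ranking.index) & set(tissues[b].ranking.index)
    seed = config.stage_seed("overlap")

    def filtered(tr: TissueReport, which: str) -> set[str]:
        de = tr.de_table.set_index("gene")
        lst = tr.up if which == "up" else tr.down
        keep = [g for g in lst.genes
                if de.loc[g, "p_value"].min() < config.alpha
                if g in universe]
        return set(keep)

    shared_up, shared_down, cross_ov, discordant = overlap.cross_tissue_core(
        filtered(tissues[a], "up"), filtered(tissues[b], "up"),
        filtered(tissues[a], "down"), filtered(tissues[b], "down"),
        universe, n_perm=config.overlap_n_perm, seed=seed + 7)

    cat = None
    if gene_sets is not None and len(gene_sets):
        cat = overlap.category_counts(shared_up, shared_down, gene_sets)

    gsea_results: dict[str, list[gsea.EnrichmentStat]] = {}
    shared_pathways = None
    if config.do_gsea and gene_sets is not None and len(gene_sets):
        gseed = config.stage_seed("gsea")
        for name in names:
            gsea_results[name] = gsea.gsea_collection(
                tissues[name].ranking, gene_sets, n_perm=config.gsea_n_perm,
                weight_p=config.gsea_weight, seed=gseed,
                min_size=config.gsea_min_size, max_size=config.gsea_max_size)
        if len(names) > 1:
            shared_pathways = gsea.shared_enriched(
                gsea_results[a], gsea_results[b], alpha=config.alpha)

    network_report = None
    if config.do_network and len(names) > 1:
        network_report = _network_stage(counts, designs, gene_sets, truth,
                                        shared_up, config, a, b)

    manifest = {
        "config_hash": _config_hash(config),
        "master_seed": config.seed,
        "sim_seed": config.simulate.seed,
        "stage_seeds": {k: config.stage_seed(k) for k in _STAGE_SEEDS},
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    logger.info("run_all finished in %.1fs", time.time() - t0)
    bundle = ReportBundle(
        config=config, tissues=tissues, shared_up=shared_up,
        shared_down=shared_down, cross_overlap=cross_ov, discordant=discordant,
        category_counts=cat, gsea_results=gsea_results,
        shared_pathways=shared_pathways, network_report=network_report,
        truth=truth, manifest=manifest)
    if config.outdir:
        write_bundle(bundle, config.outdir)
    return bundle


def _network_stage(counts, designs, gene_sets, truth, shared_up, config, a, b):
    """Condition-specific networks on the module (or the shared-up core)."""
    la, lb = log_cpm(counts[a]), log_cpm(counts[b])
    common = [g for g in la.gene_ids if g in set(lb.gene_ids)]
    combined = ExpressionMatrix(
        pd.concat([la.data.loc[common], lb.data.loc[common]], axis=1),
        scale="logcpm")
    design = pd.concat([designs[a], designs[b]], ignore_index=True)
    module = (truth.module_members if truth is not None
              else (sorted(gene_sets["MODULE_MAIN"]) if gene_sets is not None
                    and "MODULE_MAIN" in gene_sets else sorted(shared_up)))
    module = [g for g in module if g in set(common)]
    if len(module) < 3:
        return None
    dm = design.set_index("sample")
    plus = [s for s in combined.sample_ids if dm.loc[s, "phenotype"] == "PKH26_plus"]
    minus = [s for s in combined.sample_ids if dm.loc[s, "phenotype"] == "PKH26_minus"]

    report: dict = {"module_genes": module}
    # centralities + rewiring at the conventional threshold
    net_p = network.build_coexpression_network(combined, module, plus,
                                               config.r_threshold, "plus")
    net_m = network.build_coexpression_network(combined, module, minus,
                                               config.r_threshold, "minus")
    cent_p = network.betweenness_centrality(net_p).join(
        network.clustering_coefficients(net_p)["clustering"])
    cent_m = network.betweenness_centrality(net_m).join(
        network.clustering_coefficients(net_m)["clustering"])
    report["networks"] = {"plus": net_p, "minus": net_m}
    report["centrality"] = {"plus": cent_p, "minus": cent_m}
    report["rewiring"] = network.rewiring_report(cent_p, cent_m)
    report["edge_counts"] = network.edge_count_comparison(
        combined, design, module, config.r_threshold)
    # quasi-deterministic core at the elevated threshold
    core_p = network.build_coexpression_network(combined, module, plus,
                                                config.r_threshold_core, "plus")
    core_m = network.build_coexpression_network(combined, module, minus,
                                                config.r_threshold_core, "minus")
    report["core_partition"] = network.class_partition(core_p, core_m, module)
    if gene_sets is not None and len(gene_sets):
        pathway_sets = GeneSetCollection(
            {k: v for k, v in gene_sets.sets.items() if not k.startswith("DECOY")},
            {k: v for k, v in gene_sets.labels.items() if not k.startswith("DECOY")})
        cp = report["core_partition"]
        classes = {
            "plus": sorted(set(cp.plus_only) | set(cp.shared)),
            "minus": sorted(set(cp.minus_only) | set(cp.shared)),
            "all": sorted(set(network.giant_component(
                network.build_coexpression_network(
                    combined, module, None, config.r_threshold_core, "all"))[0])),
        }
        if len(pathway_sets):
            counts_tbl, corr = network.pathway_distribution(classes, pathway_sets)
            report["pathway_distribution"] = counts_tbl
            report["pathway_corr"] = corr
    return report


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> None:
    """Materialize the bundle as TSV/JSON files under ``outdir``."""
    out = Path(outdir)
    for tissue, tr in bundle.tissues.items():
        d = out / tissue
        d.mkdir(parents=True, exist_ok=True)
        tr.variance_table.to_csv(d / "variance_table.tsv", sep="\t", index=False)
        tr.loadings.round(6).to_csv(d / "loadings.tsv", sep="\t")
        tr.de_table.round(6).to_csv(d / "diffexp.tsv", sep="\t", index=False)
        tr.up.as_series().round(6).to_csv(d / "rank_up.tsv", sep="\t")
        tr.down.as_series().round(6).to_csv(d / "rank_down.tsv", sep="\t")
        disc = {"component": tr.discriminant.component,
                "orientation": tr.discriminant.orientation,
                "matched": tr.discriminant.matched,
                "candidates": tr.discriminant.candidates}
        if tr.route_overlap_up is not None:
            disc["route_overlap_up"] = tr.route_overlap_up.to_dict()
            disc["route_overlap_down"] = tr.route_overlap_down.to_dict()
        (d / "discriminant.json").write_text(json.dumps(disc, indent=1))
    cross = out / "cross_tissue"
    cross.mkdir(parents=True, exist_ok=True)
    (cross / "shared_sets.json").write_text(json.dumps(
        {"shared_up": sorted(bundle.shared_up),
         "shared_down": sorted(bundle.shared_down),
         "discordant": sorted(bundle.discordant),
         "overlap": {k: v.to_dict() for k, v in bundle.cross_overlap.items()}},
        indent=1))
    if bundle.category_counts is not None:
        bundle.category_counts.to_csv(cross / "category_counts.tsv", sep="\t",
                                      index=False)
    for tissue, res in bundle.gsea_results.items():
        gsea.results_frame(res).round(6).to_csv(
            cross / f"gsea_{tissue}.tsv", sep="\t", index=False)
    if bundle.shared_pathways is not None:
        pos, neg, stats_d = bundle.shared_pathways
        (cross / "shared_pathways.json").write_text(json.dumps(
            {"positive": sorted(pos), "negative": sorted(neg),
             "overlap": {k: v.to_dict() for k, v in stats_d.items()}}, indent=1))
    if bundle.network_report is not None:
        nd = out / "network"
        nd.mkdir(parents=True, exist_ok=True)
        rep = bundle.network_report
        for state, net in rep["networks"].items():
            network.write_sif(net, nd / f"edges_{state}.sif")
            net.edge_frame().round(6).to_csv(nd / f"edges_{state}.tsv",
                                             sep="\t", index=False)
        for state, cent in rep["centrality"].items():
            cent.round(6).to_csv(nd / f"centrality_{state}.tsv", sep="\t")
        rep["rewiring"].round(6).to_csv(nd / "rewiring.tsv", sep="\t")
        cp = rep["core_partition"]
        (nd / "core_partition.json").write_text(json.dumps(
            {"plus_only": cp.plus_only, "minus_only": cp.minus_only,
             "shared": cp.shared,
             "overlap": cp.overlap.to_dict() if cp.overlap else None}, indent=1))
        (nd / "edge_counts.json").write_text(json.dumps(
            {"edges": rep["edge_counts"]["edges"],
             "densities": rep["edge_counts"]["densities"],
             "intra_exceeds_pooled": rep["edge_counts"]["intra_exceeds_pooled"]},
            indent=1))
        if "pathway_distribution" in rep:
            rep["pathway_distribution"].to_csv(nd / "pathway_distribution.tsv",
                                               sep="\t")
            rep["pathway_corr"].round(6).to_csv(nd / "pathway_corr.tsv", sep="\t")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=1))
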