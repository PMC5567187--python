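"""End-to-end orchestration of the double-hit analysis on one run directory.

Stages run in a fixed order — simulate, qc, dmp, cluster, enrich,
integrate, network, validate, report — each writing its tables under the
run directory and its summary into ``results.json``. Every scalar
threshold of the analysis lives in :class:`PipelineConfig` and defaults to
the published value, so the default run is the reference analysis; the
full configuration (and the seed) is serialized into ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as dio
from .cluster import cluster_separation_test, hierarchical_cluster, pca, select_k_and_label
from .dmp import call_dmps, gene_probe_report
from .enrichment import GeneSetCollection, SpecificitySetConfig, build_specificity_sets, enrich, filter_brain_sets
from .gwas import candidate_filter, double_hit_overlap, filter_gwas, probe_snp_colocalization
from .network import build_network, degree_prioritize, spearman_matrix
from .qc import FilterThresholds, preprocess
from .synthetic import (
    AtlasSimConfig,
    GwasSimConfig,
    MethylSimConfig,
    simulate_coexpression_blocks,
    simulate_expression_atlas,
    simulate_gwas,
    simulate_methylation,
    simulate_gmt,
    simulate_validation_sets,
)
from .validation import ValidationSet, validate_genes

logger = logging.getLogger("doublehit")

STAGES = ("simulate", "qc", "dmp", "cluster", "enrich", "integrate", "network", "validate", "report")

#: What each stage needs to have run before it.
STAGE_DEPS = {
    "qc": ("simulate",),
    "dmp": ("qc",),
    "cluster": ("dmp",),
    "enrich": ("dmp",),
    "integrate": ("dmp",),
    "network": ("integrate",),
    "validate": ("dmp",),
    "report": (),
}


@dataclass
class PipelineConfig:
    """Every tunable of the analysis, defaulting to the reference values."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # QC
    max_missing_frac: float = 0.20
    max_snp_maf: float = 0.10
    knn_k: int = 3
    combat: bool = True
    combat_scale: str = "beta"  # or "logit"
    # DMP
    contrast: str = "FTDALS_vs_control"
    alpha: float = 0.05
    welch: bool = False
    marker_genes: tuple[str, ...] = ("GRN", "MAPT", "C9ORF72")
    # clustering
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    linkage_method: str = "average"
    linkage_metric: str = "euclidean"
    # enrichment
    fold_threshold: float = 1.5
    brain_keywords: tuple[str, ...] = ("NEURO", "BRAIN")
    # GWAS integration
    gwas_p_threshold: float = 0.05
    cadd_threshold: float = 15.0
    gene_universe_size: int | None = None  # None -> size of the simulated gene universe
    coloc_window: int = 0
    genome_build: str = "hg19-like"
    # network
    r_min: float = 0.6
    p_max: float = 0.001
    # simulators
    methyl: MethylSimConfig = field(default_factory=MethylSimConfig)
    gwas: GwasSimConfig = field(default_factory=GwasSimConfig)
    atlas: AtlasSimConfig = field(default_factory=AtlasSimConfig)
    n_validation_sets: int = 4

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build from a plain mapping; unknown keys are rejected."""
        data = dict(data)
        kwargs = {}
        for sub, subcls in (("methyl", MethylSimConfig), ("gwas", GwasSimConfig), ("atlas", AtlasSimConfig)):
            if sub in data:
                sub_data = data.pop(sub)
                known = {f.name for f in dataclasses.fields(subcls)}
                bad = set(sub_data) - known
                if bad:
                    raise ValueError(f"unknown {sub} config keys: {sorted(bad)}")
                kwargs[sub] = subcls(**sub_data)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("stages", "k_range", "brain_keywords", "marker_genes"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_stage_deps(stages: tuple[str, ...]) -> None:
    enabled = set(stages)
    unknown = enabled - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage in stages:
        missing = [d for d in STAGE_DEPS.get(stage, ()) if d not in enabled]
        if missing:
            raise ValueError(f"stage {stage!r} requires disabled stage(s): {missing}")


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    Idempotent for a fixed config and seed: reruns produce identical
    ``results.json``. A failing stage halts the run with the stage named;
    partial outputs are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(s for s in STAGES if s in set(cfg.stages))
    _check_stage_deps(stages)
    results: dict = {"stages_run": list(stages)}
    state: dict = {}

    for stage in stages:
        logger.info("stage %s", stage)
        try:
            _STAGE_FNS[stage](cfg, out, state, results)
        except Exception as exc:
            dio.write_json(results, out / "results.json")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    dio.write_json(results, out / "results.json")
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "stages": list(stages),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    dio.write_json(manifest, out / "manifest.json")
    return out


# --- stages ----------------------------------------------------------------

def _stage_simulate(cfg, out, state, results):
    methyl_cfg = dataclasses.replace(cfg.methyl, seed=cfg.seed)
    beta, ann, truth = simulate_methylation(methyl_cfg)
    gene_universe = sorted({g for g in ann["gene_symbol"] if g})
    gwas_cfg = dataclasses.replace(cfg.gwas, seed=cfg.seed + 1)
    # the double-hit structure is planted: risk genes are drawn from the
    # genes carrying truly differential probes, so GWAS and methylation
    # signals overlap by construction (as the double-hit model posits)
    truth_genes = sorted({g for p in truth for g in str(ann.at[p, "gene_symbol"]).split(";") if g})
    pool = truth_genes if truth_genes else gene_universe
    n_risk = min(cfg.gwas.n_risk_genes, len(pool))
    risk_genes = list(pd.Series(pool).sample(n=n_risk, random_state=cfg.seed + 2))
    snps = simulate_gwas(gwas_cfg, gene_universe, risk_genes=risk_genes)
    atlas_cfg = dataclasses.replace(cfg.atlas, seed=cfg.seed + 3)
    # the atlas shares the GENE%05d namespace with the cohort annotation, so
    # enrichment and network queries overlap the atlas genes naturally
    expr, tissues, atlas_truth = simulate_expression_atlas(atlas_cfg)

    state.update(beta=beta, ann=ann, truth=truth, snps=snps,
                 expr=expr, tissues=tissues, gene_universe=gene_universe,
                 risk_genes=risk_genes)
    dio.write_matrix_tsv(beta.values, out / "beta_raw.tsv")
    dio.write_matrix_tsv(beta.sample_meta, out / "sample_meta.tsv")
    dio.write_matrix_tsv(ann, out / "probe_annotation.tsv")
    dio.write_table_tsv(snps, out / "gwas_snps.tsv")
    results["simulate"] = {
        "n_probes": int(beta.values.shape[0]),
        "n_samples": int(beta.values.shape[1]),
        "n_true_dmp": len(truth),
        "n_snps": len(snps),
        "n_risk_genes": len(risk_genes),
    }


def _stage_qc(cfg, out, state, results):
    processed, report = preprocess(
        state["beta"], state["ann"],
        thresholds=FilterThresholds(cfg.max_missing_frac, cfg.max_snp_maf),
        knn_k=cfg.knn_k, adjust_batches=cfg.combat, combat_scale=cfg.combat_scale,
    )
    state["processed"] = processed
    dio.write_matrix_tsv(processed.values, out / "beta_processed.tsv")
    dio.write_json(report.to_dict(), out / "filter_report.json")
    results["qc"] = report.to_dict()


def _stage_dmp(cfg, out, state, results):
    res = call_dmps(state["processed"], state["ann"], contrast=cfg.contrast,
                    alpha=cfg.alpha, welch=cfg.welch)
    state["dmp"] = res
    flat = res.records.drop(columns=["gene_symbols"]).assign(
        gene_symbols=res.records["gene_symbols"].map(";".join))
    dio.write_matrix_tsv(flat, out / "dmp_records.tsv")
    dio.write_json(res.summary(), out / "dmp_summary.json")
    marker_report = gene_probe_report(res, list(cfg.marker_genes))
    dio.write_table_tsv(marker_report, out / "marker_gene_probes.tsv")
    # recovery against the planted truth (available in simulated runs)
    truth = state.get("truth", {})
    recovered = len(set(truth) & res.significant_probes)
    results["dmp"] = res.summary() | {
        "n_truth_probes": len(truth),
        "n_truth_recovered": recovered,
        "recovery_rate": recovered / len(truth) if truth else None,
    }


def _stage_cluster(cfg, out, state, results):
    res = state["dmp"]
    sig = sorted(res.significant_probes)
    if len(sig) < 2:  # fall back to the most-associated probes
        sig = list(res.records.sort_values("p").index[:50])
    sub = state["processed"].values.loc[sig].T  # samples x probes
    tree = hierarchical_cluster(sub, method=cfg.linkage_method, metric=cfg.linkage_metric)
    clustering = select_k_and_label(tree, sub, k_range=list(cfg.k_range))
    groups = state["processed"].groups()
    case_label = state["processed"].sample_meta["group"].loc[
        lambda s: s != "control"].unique()
    target = case_label[0] if len(case_label) else "control"
    sep_p = cluster_separation_test(clustering.labels.to_numpy(), groups.to_numpy(), target=target)
    clustering.separation_p = sep_p
    p = pca(sub, n_components=2)
    dio.write_matrix_tsv(clustering.labels.to_frame(), out / "cluster_labels.tsv")
    dio.write_matrix_tsv(p.component_scores, out / "pca_scores.tsv")
    dio.write_table_tsv(
        pd.DataFrame({"k": list(clustering.db_index_by_k),
                      "davies_bouldin": list(clustering.db_index_by_k.values())}),
        out / "db_curve.tsv")
    results["cluster"] = {
        "k_star": clustering.k_star,
        "db_index_by_k": {str(k): v for k, v in clustering.db_index_by_k.items()},
        "separation_p": sep_p,
        "flat_db_curve": clustering.flat_db_curve,
        "pca_explained_variance_ratio": list(map(float, p.explained_variance_ratio)),
    }
    state["clustering"] = clustering


def _stage_enrich(cfg, out, state, results):
    res = state["dmp"]
    query = sorted(res.significant_genes)
    out_block = {}
    if query:
        spec_cfg = SpecificitySetConfig(fold_threshold=cfg.fold_threshold, alpha=cfg.alpha)
        tissue_sets = build_specificity_sets(state["expr"], state["tissues"], spec_cfg, name="tissue")
        if tissue_sets.sets:
            tissue_table = enrich(query, tissue_sets)
            dio.write_table_tsv(tissue_table.assign(
                overlap_genes=tissue_table["overlap_genes"].map(";".join)),
                out / "tissue_enrichment.tsv")
            out_block["tissue"] = {
                "n_sets": len(tissue_sets.sets),
                "n_significant": int((tissue_table["p_bh"] < cfg.alpha).sum()),
                "top_set": tissue_table.iloc[0]["set_name"],
            }
        gmt = simulate_gmt(state["gene_universe"], planted_query=query[:30], seed=cfg.seed + 4)
        collection = GeneSetCollection("pathways", gmt, universe_size=len(state["gene_universe"]))
        keywords = tuple(cfg.brain_keywords) + ("PLANTED",)
        filtered = filter_brain_sets(collection, keywords)
        if filtered.sets:
            path_table = enrich(query, filtered)
            dio.write_table_tsv(path_table.assign(
                overlap_genes=path_table["overlap_genes"].map(";".join)),
                out / "pathway_enrichment.tsv")
            out_block["pathways"] = {
                "n_sets": len(filtered.sets),
                "n_significant": int((path_table["p_bh"] < cfg.alpha).sum()),
            }
    results["enrich"] = out_block or {"skipped": "no significant genes"}


def _stage_integrate(cfg, out, state, results):
    res = state["dmp"]
    snps = state["snps"]
    retained, gwas_genes = filter_gwas(snps, p_threshold=cfg.gwas_p_threshold)
    dmp_genes = {g.upper() for g in res.significant_genes}
    M = cfg.gene_universe_size or len(state["gene_universe"])
    block = {"n_snps_retained": len(retained), "n_gwas_genes": len(gwas_genes)}
    if gwas_genes and dmp_genes:
        overlap = double_hit_overlap(gwas_genes, dmp_genes, M=M)
        block["overlap"] = {k: overlap[k] for k in ("M", "K", "N", "x", "p")}
    candidates = candidate_filter(snps, res, p_threshold=cfg.gwas_p_threshold,
                                  cadd_threshold=cfg.cadd_threshold, alpha=cfg.alpha)
    coloc = probe_snp_colocalization(retained, state["ann"], window=cfg.coloc_window)
    state["candidates"] = candidates
    dio.write_table_tsv(candidates, out / "candidate_genes.tsv")
    dio.write_table_tsv(coloc, out / "snp_probe_colocalization.tsv")
    block.update(
        n_candidate_snps=len(candidates),
        n_candidate_genes=int(candidates["gene_symbol"].nunique()),
        n_hyper_genes=int(candidates.loc[candidates["direction"] == "hyper", "gene_symbol"].nunique()),
        n_hypo_genes=int(candidates.loc[candidates["direction"] == "hypo", "gene_symbol"].nunique()),
        n_planted_risk_recovered=len(set(candidates["gene_symbol"])
                                     & {g.upper() for g in state["risk_genes"]}),
        n_colocalizations=len(coloc),
    )
    results["integrate"] = block


def _stage_network(cfg, out, state, results):
    res = state["dmp"]
    query = sorted({g.upper() for g in res.significant_genes})
    if len(query) < 2:
        results["network"] = {"skipped": "fewer than 2 significant genes"}
        return
    # brain-region-like expression over the query genes, with co-expression
    # planted among the leading genes so the degree ranking has structure
    block = min(10, max(2, len(query) // 3))
    net_expr, _blocks = simulate_coexpression_blocks(
        n_samples=100, block_size=block, n_blocks=1, block_r=0.9,
        seed=cfg.seed + 6, genes=query)
    rho, p = spearman_matrix(net_expr)
    candidates = state.get("candidates")
    attrs = None
    if candidates is not None and len(candidates):
        attrs = (candidates.drop_duplicates("gene_symbol")
                 .set_index("gene_symbol")[["direction", "cadd"]])
        attrs["has_snp"] = True
    net = build_network(rho, p, r_min=cfg.r_min, p_max=cfg.p_max, node_attrs=attrs)
    degrees = degree_prioritize(net)
    dio.write_table_tsv(degrees, out / "gene_degrees.tsv")
    edges = pd.DataFrame(
        [{"gene_a": a, "gene_b": b, **d} for a, b, d in net.edges(data=True)])
    dio.write_table_tsv(edges, out / "network_edges.tsv")
    try:
        import networkx as nx
        nx.write_graphml(net, out / "network.graphml")
    except Exception:  # GraphML chokes on NaN attrs; edge list above is canonical
        logger.warning("GraphML export failed; edge list written instead")
    if candidates is not None and len(candidates):
        merged = candidates.merge(degrees.rename(columns={"gene": "gene_symbol"}),
                                  on="gene_symbol", how="left")
        dio.write_table_tsv(merged, out / "candidate_genes.tsv")
        state["candidates"] = merged
    results["network"] = {
        "n_query_genes": len(query),
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "top_degree_genes": degrees.head(5).to_dict("records"),
    }


def _stage_validate(cfg, out, state, results):
    res = state["dmp"]
    query = sorted({g.upper() for g in res.significant_genes})
    if not query:
        results["validate"] = {"skipped": "no significant genes"}
        return
    raw_sets, truth = simulate_validation_sets(query, n_sets=cfg.n_validation_sets,
                                               seed=cfg.seed + 5)
    sets = [ValidationSet(name, expr, labels) for name, expr, labels in raw_sets]
    outcome = validate_genes(query, sets, alpha=cfg.alpha)
    dio.write_table_tsv(outcome.ranking, out / "validation_ranking.tsv")
    results["validate"] = {
        "n_query": len(query),
        "n_validated": outcome.n_validated,
        "fisher_p_by_set": outcome.fisher_p_by_set,
        "de_counts": {k: len(v) for k, v in outcome.de_genes_by_set.items()},
    }
    state["validation"] = outcome


def _stage_report(cfg, out, state, results):
    results["report_file"] = "report.md"
    (out / "report.md").write_text(render_report(results))


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "dmp": _stage_dmp,
    "cluster": _stage_cluster,
    "enrich": _stage_enrich,
    "integrate": _stage_integrate,
    "network": _stage_network,
    "validate": _stage_validate,
    "report": _stage_report,
}


def render_report(results: dict) -> str:
    """Human-readable run summary; every number restates a results.json
    field — nothing is recomputed here."""
    lines = ["# Double-hit pipeline run report", ""]

    def section(title, key, fields):
        lines.append(f"## {title}")
        block = results.get(key)
        if not block:
            lines.append("_absent (stage not run)_")
        elif "skipped" in block:
            lines.append(f"_skipped: {block['skipped']}_")
        else:
            for label, path in fields:
                val = block
                for part in path.split("."):
                    val = val.get(part) if isinstance(val, dict) else None
                    if val is None:
                        break
                lines.append(f"- {label}: {val}")
        lines.append("")

    section("Inputs", "simulate", [
        ("probes", "n_probes"), ("samples", "n_samples"),
        ("planted differential probes", "n_true_dmp"), ("GWAS SNPs", "n_snps")])
    section("Probe QC", "qc", [
        ("input probes", "input_probes"), ("retained probes", "retained_probes"),
        ("retained genes", "retained_genes")])
    section("Differential methylation", "dmp", [
        ("tests", "n_tests"), ("significant probes", "n_significant_probes"),
        ("significant genes", "n_significant_genes"),
        ("hypermethylated probes", "n_hyper_probes"),
        ("hypomethylated probes", "n_hypo_probes"),
        ("planted-truth recovery", "recovery_rate")])
    section("Class discovery", "cluster", [
        ("chosen k", "k_star"), ("cluster/diagnosis separation p", "separation_p")])
    section("Enrichment", "enrich", [
        ("significant tissue sets", "tissue.n_significant"),
        ("significant pathway sets", "pathways.n_significant")])
    section("GWAS integration (double hit)", "integrate", [
        ("retained SNPs", "n_snps_retained"), ("GWAS genes", "n_gwas_genes"),
        ("overlap x", "overlap.x"), ("overlap p", "overlap.p"),
        ("candidate SNPs", "n_candidate_snps"), ("candidate genes", "n_candidate_genes"),
        ("hypermethylated candidates", "n_hyper_genes"),
        ("hypomethylated candidates", "n_hypo_genes"),
        ("SNP/probe colocalizations", "n_colocalizations")])
    section("Co-expression network", "network", [
        ("nodes", "n_nodes"), ("edges", "n_edges")])
    section("Expression validation", "validate", [
        ("query genes", "n_query"), ("validated genes", "n_validated")])
    return "\n".join(lines)
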