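"""End-to-end workflow: preprocess -> differential -> patterns -> PAGE ->
pathway patterns -> target integration -> network.

A single :class:`PipelineConfig` records every threshold and seed; the run
writes all intermediate tables plus a machine-readable JSON report of the
counts at each step, and is byte-for-byte deterministic given the config.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import pandas as pd

from . import io as iom
from .differential import anova_per_feature, attribute_transitions, tukey_hsd, venn_partition
from .integration import (
    derive_target_pathways,
    filter_targets_by_context_score,
    integrate_mirna_mrna,
    rank_top_pathways,
    target_pathway_names,
)
from .model import (
    ExpressionMatrix,
    GeneSet,
    PatternAssignment,
    StageDesign,
    TargetPrediction,
    transition_name,
)
from .network import build_network
from .pathways import page_scores
from .patterns import assign_patterns
from .preprocess import quantile_normalize, remove_zero_variance, sd_quantile_filter


@dataclass
class PipelineConfig:
    """All thresholds and seeds of the workflow (defaults are the study's
    printed values)."""

    seed: int = 17
    fdr: float = 0.05
    tukey_alpha: float = 0.01
    lfc: float = 2.0
    silhouette: float = 0.5
    target_quantile: float = 0.05
    min_match: float = 0.9
    min_abs_r: float = 0.7
    k: int = 8
    k_pathways: int = 8
    n_restarts: int = 25
    sd_quantile: float = 0.25
    quantile_normalize_genes: bool = True
    min_set_members: int = 3
    n_top_pathways: int = 2
    outdir: str | None = None

    def validate(self) -> None:
        for name, lo, hi in [
            ("fdr", 0, 1), ("tukey_alpha", 0, 1), ("silhouette", -1, 1),
            ("target_quantile", 0, 1), ("min_match", -1, 1), ("min_abs_r", 0, 1),
            ("sd_quantile", 0, 1),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.k < 2 or self.k_pathways < 2:
            raise ValueError("k must be >= 2")


@dataclass
class PipelineResult:
    report: dict
    mirna_assignment: PatternAssignment
    gene_assignment: PatternAssignment
    pathway_assignment: PatternAssignment
    triples: pd.DataFrame
    expanded_triples: pd.DataFrame
    pathway_scores: ExpressionMatrix
    top_pathways: dict[str, pd.DataFrame]
    network: "object"


def run_pipeline(
    mirna: ExpressionMatrix,
    gene: ExpressionMatrix,
    design: StageDesign,
    predictions: list[TargetPrediction],
    gene_sets: list[GeneSet],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute the full workflow on in-memory inputs.

    Returns a :class:`PipelineResult`; when ``config.outdir`` is set, all
    intermediate tables, the verbatim config and the JSON report are
    written there.
    """
    config = config or PipelineConfig()
    config.validate()
    report: dict = {"config": dataclasses.asdict(config)}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # --- miRNA arm -------------------------------------------------------
    mirna_f, zv_report = stage("mirna_zero_variance", remove_zero_variance, mirna)
    report["mirna_filter"] = dataclasses.asdict(zv_report)
    mirna_anova = stage("mirna_anova", anova_per_feature, mirna_f, design)
    mirna_sig = mirna_anova.index[mirna_anova["q"] < config.fdr]
    report["mirna_significant"] = int(len(mirna_sig))
    mirna_sig_matrix = mirna_f.subset(features=mirna_sig)
    mirna_pairwise = stage("mirna_tukey", tukey_hsd, mirna_f, design)
    mirna_calls = stage(
        "mirna_transitions",
        attribute_transitions,
        mirna_pairwise, mirna_anova, design,
        lfc_threshold=config.lfc, alpha=config.tukey_alpha,
        anova_q_threshold=config.fdr,
    )
    report["mirna_transition_altered"] = len(mirna_calls)
    per_transition = {transition_name(t): 0 for t in design.transitions()}
    for callset in mirna_calls.values():
        for name, _ in callset:
            per_transition[name] += 1
    report["mirna_calls_per_transition"] = per_transition
    venn = venn_partition(mirna_calls, design)
    report["mirna_venn"] = {"|".join(k): v for k, v in venn.items()}
    mirna_assignment = stage(
        "mirna_patterns",
        assign_patterns,
        mirna_sig_matrix, design,
        k=min(config.k, max(len(mirna_sig), 2)), seed=config.seed,
        n_restarts=config.n_restarts, min_match=config.min_match,
    )
    report["mirna_groups"] = mirna_assignment.counts()

    # --- gene arm --------------------------------------------------------
    gene_n = stage("gene_quantile_normalize", quantile_normalize, gene) \
        if config.quantile_normalize_genes else gene
    gene_f, sd_report = stage(
        "gene_sd_filter", sd_quantile_filter, gene_n, config.sd_quantile
    )
    report["gene_filter"] = dataclasses.asdict(sd_report)
    gene_anova = stage("gene_anova", anova_per_feature, gene_f, design)
    gene_sig = gene_anova.index[gene_anova["q"] < config.fdr]
    report["gene_significant"] = int(len(gene_sig))
    gene_pairwise = stage("gene_tukey", tukey_hsd, gene_f, design)
    gene_calls = stage(
        "gene_transitions",
        attribute_transitions,
        gene_pairwise, gene_anova, design,
        lfc_threshold=config.lfc, alpha=config.tukey_alpha,
        anova_q_threshold=config.fdr,
    )
    report["gene_transition_altered"] = len(gene_calls)
    gene_assignment = stage(
        "gene_patterns",
        assign_patterns,
        gene_f.subset(features=gene_sig), design,
        k=min(config.k, max(len(gene_sig), 2)), seed=config.seed + 1,
        n_restarts=config.n_restarts, min_match=config.min_match,
        reversed_semantics=True,
    )
    report["gene_groups"] = gene_assignment.counts()

    # --- pathway arm -----------------------------------------------------
    scores, page_report = stage(
        "page", page_scores, gene_f, gene_sets, config.min_set_members
    )
    report["page_filter"] = dataclasses.asdict(page_report)
    pathway_assignment = stage(
        "pathway_patterns",
        assign_patterns,
        scores, design,
        k=min(config.k_pathways, max(scores.shape[0], 2)), seed=config.seed + 2,
        n_restarts=config.n_restarts, min_match=config.min_match,
        reversed_semantics=True, silhouette_threshold=config.silhouette,
    )
    report["pathways_assigned"] = int(len(pathway_assignment.assigned))

    # --- integration -----------------------------------------------------
    filtered = stage(
        "target_filter",
        filter_targets_by_context_score,
        predictions, config.target_quantile,
    )
    report["target_predictions"] = {
        "input": len(predictions),
        "after_context_filter": len(filtered),
    }
    triples = stage(
        "integrate", integrate_mirna_mrna,
        mirna_assignment, gene_assignment, filtered, design,
    )
    report["integrated_pairs"] = int(len(triples))
    report["integrated_genes"] = int(triples["gene"].nunique()) if len(triples) else 0
    expanded = stage(
        "target_pathways", derive_target_pathways,
        triples, pathway_assignment, gene_sets,
    )
    report["target_pathways"] = sorted(target_pathway_names(expanded))
    report["n_target_pathways"] = len(report["target_pathways"])

    top = {}
    for pair in design.transitions():
        ranking = stage(
            "rank_pathways", rank_top_pathways,
            scores, design, pair,
            n_top=config.n_top_pathways, lfc=config.lfc, alpha=config.tukey_alpha,
            pathways=report["target_pathways"],
        )
        top[transition_name(pair)] = ranking
    report["top_pathways"] = {
        t: ranking["pathway"].tolist() for t, ranking in top.items()
    }

    graph = stage(
        "network", build_network,
        expanded, mirna, gene_n, scores, min_abs_r=config.min_abs_r,
    )
    report["network"] = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
    }

    result = PipelineResult(
        report=report,
        mirna_assignment=mirna_assignment,
        gene_assignment=gene_assignment,
        pathway_assignment=pathway_assignment,
        triples=triples,
        expanded_triples=expanded,
        pathway_scores=scores,
        top_pathways=top,
        network=graph,
    )
    if config.outdir:
        _write_outputs(result, mirna_f, gene_f, mirna_anova, gene_anova,
                       mirna_pairwise, gene_pairwise, config)
    return result


def _write_outputs(result, mirna_f, gene_f, mirna_anova, gene_anova,
                   mirna_pairwise, gene_pairwise, config):
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    iom.write_expression_matrix(mirna_f, os.path.join(outdir, "mirna_filtered.tsv"))
    iom.write_expression_matrix(gene_f, os.path.join(outdir, "gene_filtered.tsv"))
    mirna_anova.to_csv(os.path.join(outdir, "mirna_anova.tsv"), sep="\t")
    gene_anova.to_csv(os.path.join(outdir, "gene_anova.tsv"), sep="\t")
    mirna_pairwise.to_csv(os.path.join(outdir, "mirna_tukey.tsv"), sep="\t", index=False)
    gene_pairwise.to_csv(os.path.join(outdir, "gene_tukey.tsv"), sep="\t", index=False)
    result.mirna_assignment.table.to_csv(os.path.join(outdir, "mirna_patterns.tsv"), sep="\t")
    result.gene_assignment.table.to_csv(os.path.join(outdir, "gene_patterns.tsv"), sep="\t")
    result.pathway_assignment.table.to_csv(os.path.join(outdir, "pathway_patterns.tsv"), sep="\t")
    iom.write_expression_matrix(result.pathway_scores, os.path.join(outdir, "pathway_scores.tsv"))
    result.expanded_triples.to_csv(os.path.join(outdir, "triples.tsv"), sep="\t", index=False)
    iom.write_network_edgelist(result.network, os.path.join(outdir, "network.edges.tsv"))
    with open(os.path.join(outdir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)


def run_pipeline_from_paths(
    mirna_path, gene_path, design_path, targets_path, gmt_path,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """File-based entry point used by the command line."""
    mirna = iom.read_expression_matrix(mirna_path, kind="miRNA")
    gene = iom.read_expression_matrix(gene_path, kind="gene")
    design = iom.read_stage_design(design_path)
    predictions = iom.read_target_predictions(targets_path)
    gene_sets = iom.read_gmt(gmt_path)
    return run_pipeline(mirna, gene, design, predictions, gene_sets, config)
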