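"""End-to-end orchestration of the hub-gene discovery analysis.

Stage order mirrors the analysis flow: differential calling over the
time course, model-profile clustering of the differential genes,
gene-set enrichment of the clustered genes, co-expression network +
k-core hub selection over the genes inside significant terms,
literature overlap + PPI subnetwork extraction, pathway enrichment of
the overlap genes, and optional qPCR concordance. Every intermediate
table is written to the output directory and per-stage gene counts are
logged; output is byte-identical for identical config + inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import diffexpr, enrichment, network, ppi, profiles, qpcr
from .config import RunConfig
from .io import (
    AnnotationCollection,
    ExpressionMatrix,
    TermDag,
    read_ct_table,
    read_edge_list,
    read_expression,
    read_gene_list,
    read_gmt,
    read_term_dag,
)

__all__ = ["PipelineInputs", "PipelineResult", "PipelineStageError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineInputs:
    expression: ExpressionMatrix
    annotations: AnnotationCollection
    dag: TermDag
    ppi: nx.Graph
    literature: list[str]
    pathways: AnnotationCollection | None = None
    ct_table: pd.DataFrame | None = None

    @classmethod
    def from_paths(
        cls,
        expression: str | Path,
        gmt: str | Path,
        dag: str | Path,
        ppi_edges: str | Path,
        literature: str | Path,
        metadata: str | Path | None = None,
        pathways_gmt: str | Path | None = None,
        ct: str | Path | None = None,
    ) -> "PipelineInputs":
        return cls(
            expression=read_expression(expression, metadata=metadata),
            annotations=read_gmt(gmt),
            dag=read_term_dag(dag),
            ppi=read_edge_list(ppi_edges),
            literature=read_gene_list(literature),
            pathways=read_gmt(pathways_gmt, namespace="pathway") if pathways_gmt else None,
            ct_table=read_ct_table(ct) if ct else None,
        )


@dataclass
class PipelineResult:
    differential: diffexpr.DifferentialTable
    cluster: profiles.ClusterResult
    go_enrichment: pd.DataFrame
    go_map: nx.DiGraph
    selected_genes: list[str]
    coexpression: nx.Graph
    core_report: network.CoreGeneReport
    overlap: ppi.OverlapSet
    subnetwork: nx.Graph
    hubs: list[str]
    pathway_enrichment: pd.DataFrame | None = None
    qpcr_folds: pd.DataFrame | None = None
    qpcr_concordance: float | None = None
    counts: dict[str, int] = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - stage name must surface
            raise PipelineStageError(name, exc) from exc

    return wrap


def run_pipeline(
    config: RunConfig, inputs: PipelineInputs, out_dir: str | Path
) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = inputs.expression
    counts: dict[str, int] = {"genes_in": len(matrix.genes)}
    log.info("pipeline start: %d genes, %d samples", len(matrix.genes), matrix.values.shape[1])

    # 1. differential expression
    diff = _stage("diffexpr")(diffexpr.call_differential, matrix, alpha=config.alpha_de)
    diff.write(out / "differential.tsv")
    de_genes = diff.significant_genes()
    counts["differential_genes"] = len(de_genes)
    log.info("diffexpr: %d / %d genes significant at p<%g (any timepoint)",
             len(de_genes), len(matrix.genes), config.alpha_de)

    # 2. model-profile clustering of differential genes
    def _cluster():
        cands = profiles.enumerate_candidate_profiles(
            len(matrix.timepoints), config.max_unit_change
        )
        pset = profiles.select_model_profiles(
            cands, min(config.n_model_profiles, len(cands)), seed=config.seed
        )
        traj = profiles.trajectories(matrix, de_genes)
        assignment = profiles.assign_genes(traj, pset)
        return profiles.profile_significance(
            assignment, traj, pset, alpha=config.alpha_profile, seed=config.seed
        )

    cluster = _stage("stem_clustering")(_cluster)
    cluster.write(out / "profiles.tsv")
    cluster.assignment.rename("profile_id").to_csv(out / "gene_profiles.tsv", sep="\t")
    clustered = cluster.clustered_genes()
    counts["clustered_genes"] = len(clustered)
    log.info("clustering: %d significant profile(s), %d genes",
             len(cluster.significant_profiles()), len(clustered))

    # 3. GO enrichment of clustered genes; selection of genes in significant terms
    def _enrich():
        background = {g.upper() for g in matrix.genes}
        study = {g.upper() for g in clustered}
        table = enrichment.fisher_enrichment(study, inputs.annotations, background)
        sig_terms = set(table.loc[table["p_fisher"] < config.alpha_enrich, "term_id"])
        go_map = enrichment.build_go_map(sig_terms, inputs.dag)
        selected_uc = set()
        for term in sig_terms:
            selected_uc |= inputs.annotations.genes_of(term) & study
        selected = sorted(g for g in clustered if g.upper() in selected_uc)
        return table, go_map, selected

    go_table, go_map, selected = _stage("enrichment")(_enrich)
    go_table.to_csv(out / "enrichment_go.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(go_map.edges()), columns=["child", "parent"]).to_csv(
        out / "go_map_edges.tsv", sep="\t", index=False
    )
    counts["go_selected_genes"] = len(selected)
    log.info("enrichment: %d significant term(s), %d genes selected",
             go_map.number_of_nodes(), len(selected))

    # 4. co-expression network + k-core hubs on the selected genes
    def _network():
        corr = network.pairwise_correlation(matrix, selected)
        graph = network.build_network(
            corr,
            r_threshold=config.correlation_threshold,
            p_threshold=config.correlation_p_threshold,
        )
        network.annotate_network(graph)
        return graph, network.core_genes(graph)

    graph, core_report = _stage("coexpression_network")(_network)
    network.node_table(graph).to_csv(out / "network_nodes.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted((min(a, b), max(a, b)) for a, b in graph.edges()),
        columns=["gene_a", "gene_b"],
    ).to_csv(out / "network_edges.tsv", sep="\t", index=False)
    core_report.to_frame().to_csv(out / "core_genes.tsv", sep="\t", index=False)
    counts["network_genes"] = graph.number_of_nodes()
    counts["core_genes"] = len(core_report.all_core_genes())
    log.info("network: %d nodes, %d edges, %d core gene(s)",
             graph.number_of_nodes(), graph.number_of_edges(), counts["core_genes"])

    # 5. literature overlap, PPI subnetwork, hubs
    def _ppi():
        overlap = ppi.overlap_genes(de_genes, inputs.literature)
        sub = ppi.extract_seed_subnetwork(inputs.ppi, overlap.genes)
        hubs = ppi.hub_nodes(sub, min_degree=config.hub_min_degree)
        return overlap, sub, hubs

    overlap, sub, hubs = _stage("ppi_overlap")(_ppi)
    (out / "overlap_genes.txt").write_text("\n".join(sorted(overlap.genes)) + "\n")
    ppi.subnetwork_node_table(sub).to_csv(out / "ppi_subnetwork_nodes.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted((min(a, b), max(a, b)) for a, b in sub.edges()),
        columns=["gene_a", "gene_b"],
    ).to_csv(out / "ppi_subnetwork_edges.tsv", sep="\t", index=False)
    pd.Series(hubs, name="gene").to_csv(out / "ppi_hubs.tsv", sep="\t", index=False)
    counts["overlap_genes"] = len(overlap.genes)
    counts["ppi_hubs"] = len(hubs)
    log.info("ppi: %d overlap gene(s), %d hub(s) at degree >= %d",
             len(overlap.genes), len(hubs), config.hub_min_degree)

    # 6. pathway enrichment of the overlap genes (optional)
    pathway_table = None
    if inputs.pathways is not None:
        def _pathways():
            background = {g.upper() for g in matrix.genes} | {
                g.upper() for g in inputs.literature
            }
            return enrichment.pathway_enrichment(
                set(overlap.genes), inputs.pathways, background, david_style=True
            )

        pathway_table = _stage("pathway_enrichment")(_pathways)
        pathway_table.to_csv(out / "enrichment_pathways.tsv", sep="\t", index=False)

    # 7. qPCR validation (optional)
    folds = conc = None
    if inputs.ct_table is not None:
        def _qpcr():
            table = qpcr.ddct_table(inputs.ct_table)
            _, fraction = qpcr.concordance(diff, table)
            return table, fraction

        folds, conc = _stage("qpcr")(_qpcr)
        folds.to_csv(out / "qpcr_folds.tsv", sep="\t", index=False)
        log.info("qpcr: direction concordance %.3f", conc)

    pd.Series(counts, name="count").to_csv(out / "stage_counts.tsv", sep="\t")
    return PipelineResult(
        differential=diff,
        cluster=cluster,
        go_enrichment=go_table,
        go_map=go_map,
        selected_genes=selected,
        coexpression=graph,
        core_report=core_report,
        overlap=overlap,
        subnetwork=sub,
        hubs=hubs,
        pathway_enrichment=pathway_table,
        qpcr_folds=folds,
        qpcr_concordance=conc,
        counts=counts,
    )
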