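"""Correlation network construction and k-core hub-gene selection.

Genes become nodes; an edge joins two genes whose Pearson correlation
over their temporal log-ratio trajectories passes both an |r| threshold
and a correlation-test p gate. Hubs are found by k-core decomposition:
peel nodes of degree < k until every survivor has degree >= k; a node's
coreness is the largest k it survives. Within each connected subnetwork
the genes attaining the maximum coreness are the core (hub) genes.

The k-core peeling and the local clustering coefficient are implemented
here directly since they are the analysis' hub-selection machinery;
tests cross-check them against networkx and brute-force oracles.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .profiles import trajectories

__all__ = [
    "pairwise_correlation",
    "build_network",
    "clustering_coefficient",
    "kcore_decomposition",
    "core_genes",
    "annotate_network",
    "ComponentCores",
    "CoreGeneReport",
]

log = logging.getLogger(__name__)


def pairwise_correlation(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Pearson r (with a two-sided correlation-test p) for every
    unordered gene pair.

    By default genes are compared on their per-timepoint mean log-ratio
    trajectories (the same object the profile clustering uses);
    ``per_sample`` switches to per-sample log2 values. Zero-variance
    genes cannot be correlated and are excluded (logged).
    """
    if per_sample:
        data = matrix.log2()
        if genes is not None:
            data = data.loc[[g for g in genes if g in data.index]]
    else:
        data = trajectories(matrix, genes)
    n_obs = data.shape[1]
    if n_obs < 3:
        raise ValueError(f"need >= 3 observations per gene, have {n_obs}")

    values = data.to_numpy(dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        log.info(
            "excluding %d zero-variance gene(s) from correlation: %s",
            int((~keep).sum()),
            list(data.index[~keep])[:10],
        )
    names = list(data.index[keep])
    values = values[keep]
    if len(names) < 2:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r", "p", "n_obs"])

    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    iu = np.triu_indices(len(names), k=1)
    r_flat = r[iu]
    df = n_obs - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_flat * np.sqrt(df / (1.0 - r_flat**2))
    p_flat = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    return pd.DataFrame(
        {
            "gene_a": [names[i] for i in iu[0]],
            "gene_b": [names[j] for j in iu[1]],
            "r": r_flat,
            "p": p_flat,
            "n_obs": n_obs,
        }
    )


def build_network(
    correlations: pd.DataFrame,
    r_threshold: float = 0.8,
    p_threshold: float | None = 0.05,
) -> nx.Graph:
    """Threshold the correlation table into a graph.

    Edge iff |r| >= r_threshold and (when the gate is enabled) the
    correlation-test p < p_threshold. Isolated genes never enter the
    graph. An empty result is returned (with a warning) rather than
    raised."""
    keep = correlations["r"].abs() >= r_threshold
    if p_threshold is not None:
        keep &= correlations["p"] < p_threshold
    graph = nx.Graph()
    for row in correlations[keep].itertuples(index=False):
        graph.add_edge(row.gene_a, row.gene_b, r=float(row.r), p=float(row.p))
    if graph.number_of_edges() == 0:
        log.warning("no gene pair passed the correlation thresholds; empty network")
    return graph


def clustering_coefficient(graph: nx.Graph, node) -> float:
    """Local clustering coefficient 2*t / (deg*(deg-1)), where t counts
    edges among the node's neighbors; 0 for degree < 2."""
    neighbors = list(graph.neighbors(node))
    deg = len(neighbors)
    if deg < 2:
        return 0.0
    links = sum(
        1 for a, b in itertools.combinations(neighbors, 2) if graph.has_edge(a, b)
    )
    return 2.0 * links / (deg * (deg - 1))


def kcore_decomposition(graph: nx.Graph) -> dict:
    """Coreness of every node by iterative peeling.

    Remove all nodes of degree <= k (cascading) before raising k; the k
    at which a node is removed is its coreness.
    """
    work = graph.copy()
    work.remove_edges_from(nx.selfloop_edges(work))
    coreness: dict = {}
    k = 0
    while work.number_of_nodes():
        degrees = dict(work.degree())
        min_deg = min(degrees.values())
        k = max(k, min_deg)
        queue = [v for v, d in degrees.items() if d <= k]
        while queue:
            batch, queue = queue, []
            for v in batch:
                if v in coreness:
                    continue
                coreness[v] = k
                neighbors = list(work.neighbors(v))
                work.remove_node(v)
                queue.extend(u for u in neighbors if u not in coreness and work.degree(u) <= k)
    return coreness


@dataclass
class ComponentCores:
    component_id: int
    nodes: list
    max_coreness: int
    core_genes: list  # empty when the component is too small to rank
    eligible: bool


@dataclass
class CoreGeneReport:
    components: list[ComponentCores]

    def all_core_genes(self) -> list:
        out = []
        for comp in self.components:
            out.extend(comp.core_genes)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "component_id": c.component_id,
                "n_nodes": len(c.nodes),
                "max_coreness": c.max_coreness,
                "eligible": c.eligible,
                "core_genes": ";".join(map(str, c.core_genes)),
            }
            for c in self.components
        ]
        return pd.DataFrame(
            rows, columns=["component_id", "n_nodes", "max_coreness", "eligible", "core_genes"]
        )


def core_genes(
    graph: nx.Graph,
    coreness: dict | None = None,
    min_component_size: int = 3,
) -> CoreGeneReport:
    """Per connected subnetwork, the nodes attaining its maximum coreness,
    ranked by degree descending (ties alphabetical).

    Components below ``min_component_size`` are reported but yield no
    core genes (their coreness is trivial)."""
    if coreness is None:
        coreness = kcore_decomposition(graph)
    comps = sorted(
        nx.connected_components(graph),
        key=lambda c: (-len(c), min(str(v) for v in c)),
    )
    report = []
    for cid, comp in enumerate(comps, start=1):
        max_core = max(coreness[v] for v in comp)
        eligible = len(comp) >= min_component_size
        winners = []
        if eligible:
            winners = sorted(
                (v for v in comp if coreness[v] == max_core),
                key=lambda v: (-graph.degree(v), str(v)),
            )
        report.append(
            ComponentCores(
                component_id=cid,
                nodes=sorted(comp, key=str),
                max_coreness=max_core,
                core_genes=winners,
                eligible=eligible,
            )
        )
    return CoreGeneReport(report)


def annotate_network(graph: nx.Graph) -> nx.Graph:
    """Attach degree, clustering_coefficient, coreness and component_id
    node attributes in place; returns the graph."""
    coreness = kcore_decomposition(graph)
    comps = sorted(
        nx.connected_components(graph),
        key=lambda c: (-len(c), min(str(v) for v in c)),
    )
    comp_of = {v: cid for cid, comp in enumerate(comps, start=1) for v in comp}
    for v in graph.nodes:
        graph.nodes[v]["degree"] = graph.degree(v)
        graph.nodes[v]["clustering_coefficient"] = clustering_coefficient(graph, v)
        graph.nodes[v]["coreness"] = coreness[v]
        graph.nodes[v]["component_id"] = comp_of[v]
    return graph


def node_table(graph: nx.Graph) -> pd.DataFrame:
    """Table 2-shaped node summary (gene, degree, clustering coefficient,
    coreness, component), sorted by degree descending then name."""
    rows = [
        {
            "gene": v,
            "degree": graph.nodes[v].get("degree", graph.degree(v)),
            "clustering_coefficient": graph.nodes[v].get("clustering_coefficient", np.nan),
            "coreness": graph.nodes[v].get("coreness", np.nan),
            "component_id": graph.nodes[v].get("component_id", np.nan),
        }
        for v in graph.nodes
    ]
    table = pd.DataFrame(
        rows, columns=["gene", "degree", "clustering_coefficient", "coreness", "component_id"]
    )
    if len(table):
        table = table.sort_values(
            ["degree", "gene"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    return table
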