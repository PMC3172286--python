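"""Literature-overlap seed genes and PPI subnetwork extraction.

Differentially expressed genes that also appear in a literature-mined
radiation gene list ("overlapping genes") serve as seeds. The subnetwork
pulled from the full protein-protein interaction network consists of the
seeds plus their first neighbors, with every interaction among the
retained nodes kept (induced subgraph; a ``star`` mode restricts to
seed-incident edges). Hubs are then the subnetwork nodes whose degree
reaches a cutoff. All symbol comparisons are case-insensitive; an
optional mapping table (e.g. mouse-to-human orthologs) is applied before
uppercasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = ["OverlapSet", "overlap_genes", "extract_seed_subnetwork", "hub_nodes"]

log = logging.getLogger(__name__)

SEED = "seed"
NEIGHBOR = "neighbor"


@dataclass(frozen=True)
class OverlapSet:
    genes: frozenset[str]
    source_a_size: int
    source_b_size: int


def _normalize(symbols: Iterable[str], mapping: Mapping[str, str] | None) -> set[str]:
    if mapping is not None:
        mapping = {k.upper(): v.upper() for k, v in mapping.items()}
        return {mapping.get(s.upper(), s.upper()) for s in symbols}
    return {s.upper() for s in symbols}


def overlap_genes(
    list_a: Iterable[str],
    list_b: Iterable[str],
    mapping: Mapping[str, str] | None = None,
) -> OverlapSet:
    """Case-insensitive intersection of two symbol lists; duplicates
    collapse, and ``mapping`` (symbol -> symbol) is applied first."""
    a = _normalize(list_a, mapping)
    b = _normalize(list_b, mapping)
    if not a or not b:
        raise ValueError("both gene lists must be non-empty")
    return OverlapSet(genes=frozenset(a & b), source_a_size=len(a), source_b_size=len(b))


def extract_seed_subnetwork(
    ppi: nx.Graph, seeds: Iterable[str], star: bool = False
) -> nx.Graph:
    """Seeds plus first neighbors, as an induced subgraph of the PPI.

    Seeds absent from the PPI are retained as isolated seed nodes
    (logged). ``star`` keeps only edges incident to a seed, dropping
    neighbor-neighbor interactions. Node attribute ``role`` marks each
    node as seed or neighbor.
    """
    seeds = {s.upper() for s in seeds}
    present = seeds & set(ppi.nodes)
    absent = seeds - present
    if absent:
        log.info("%d seed(s) absent from the PPI kept as isolated nodes", len(absent))
    if not present:
        log.warning("no seed gene present in the PPI; subnetwork is isolated seeds only")
    neighbors: set[str] = set()
    for s in present:
        neighbors.update(ppi.neighbors(s))
    retained = present | neighbors
    sub = ppi.subgraph(retained).copy()
    if star:
        drop = [(a, b) for a, b in sub.edges if a not in seeds and b not in seeds]
        sub.remove_edges_from(drop)
    sub.add_nodes_from(absent)
    for v in sub.nodes:
        sub.nodes[v]["role"] = SEED if v in seeds else NEIGHBOR
    return sub


def hub_nodes(subnetwork: nx.Graph, min_degree: int = 11) -> list[str]:
    """Nodes with within-subnetwork degree >= min_degree, ranked by
    degree descending, ties alphabetical."""
    hubs = [v for v in subnetwork.nodes if subnetwork.degree(v) >= min_degree]
    return sorted(hubs, key=lambda v: (-subnetwork.degree(v), str(v)))


def subnetwork_node_table(subnetwork: nx.Graph) -> pd.DataFrame:
    rows = [
        {"gene": v, "role": subnetwork.nodes[v].get("role", ""), "degree": subnetwork.degree(v)}
        for v in subnetwork.nodes
    ]
    table = pd.DataFrame(rows, columns=["gene", "role", "degree"])
    if len(table):
        table = table.sort_values(
            ["degree", "gene"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    return table
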