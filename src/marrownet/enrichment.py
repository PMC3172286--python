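"""Gene-set over-representation analysis and the significant-term map.

Each term is tested with the one-tailed Fisher exact test (upper
hypergeometric tail of the 2x2 study/background table); a Pearson
chi-square p is reported alongside as an advisory statistic but never
used for selection. Benjamini-Hochberg q-values run across the tested
terms. The enrichment ratio (k/n)/(K/N) measures how specific a term is
to the study set.

``pathway_enrichment`` reuses the same machinery for pathway gene sets
and offers the conservative EASE variant (Fisher on k-1 study hits).
``build_go_map`` draws the child->parent map over significant terms:
edges follow the term hierarchy, contracted so that only the nearest
significant ancestor is kept (transitive reduction over the significant
set).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .io import AnnotationCollection, TermDag

__all__ = [
    "fisher_enrichment",
    "chi2_enrichment",
    "pathway_enrichment",
    "build_go_map",
]

log = logging.getLogger(__name__)


def chi2_enrichment(k: int, n: int, K: int, N: int) -> tuple[float, bool]:
    """Pearson chi-square p (1 df, no continuity correction) for the 2x2
    table (k, n-k; K-k, N-n-K+k).

    Returns (p, reliable); reliable is False when any expected cell is
    below 1, where the chi-square approximation breaks down.
    """
    observed = np.array([[k, n - k], [K - k, N - n - K + k]], dtype=float)
    if (observed < 0).any():
        raise ValueError(f"2x2 table has a negative cell: k={k}, n={n}, K={K}, N={N}")
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    total = observed.sum()
    expected = row @ col / total
    reliable = bool((expected >= 1).all())
    if (expected == 0).any():
        return 1.0, False
    stat = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(stat, df=1)), reliable


def _enrich(
    study: set[str],
    annotations: AnnotationCollection,
    background: set[str],
    ease: bool = False,
) -> pd.DataFrame:
    study = {g.upper() for g in study}
    background = {g.upper() for g in background}
    offenders = study - background
    if offenders:
        raise ValueError(
            f"study genes outside the background universe: {sorted(offenders)[:10]}"
            + ("..." if len(offenders) > 10 else "")
        )
    N, n = len(background), len(study)
    rows = []
    for term_id in sorted(annotations.terms):
        term_genes = annotations.genes_of(term_id) & background
        K = len(term_genes)
        if K == 0:
            log.debug("term %s has no background genes; skipped", term_id)
            continue
        hits = sorted(study & term_genes)
        k = len(hits)
        k_eff = max(k - 1, 0) if ease else k
        p_fisher = float(stats.hypergeom.sf(k_eff - 1, N, K, n)) if k_eff > 0 else 1.0
        p_chi2, chi2_ok = chi2_enrichment(k, n, K, N)
        ratio = (k / n) / (K / N) if n > 0 else np.nan
        rows.append(
            {
                "term_id": term_id,
                "term_name": annotations.name_of(term_id),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_fisher": p_fisher,
                "p_chi2": p_chi2,
                "chi2_reliable": chi2_ok,
                "enrichment_ratio": ratio,
                "hits": ";".join(hits),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "k", "n", "K", "N",
            "p_fisher", "p_chi2", "chi2_reliable", "enrichment_ratio", "hits",
        ],
    )
    if len(table):
        table["q"] = bh_fdr(table["p_fisher"].to_numpy())
        table = table.sort_values(
            ["p_fisher", "term_id"], kind="stable"
        ).reset_index(drop=True)
    else:
        table["q"] = pd.Series(dtype=float)
    return table


def fisher_enrichment(
    study: set[str], annotations: AnnotationCollection, background: set[str]
) -> pd.DataFrame:
    """One-tailed over-representation test of every term against the
    study set; terms with no background genes are skipped."""
    return _enrich(study, annotations, background, ease=False)


def pathway_enrichment(
    study: set[str],
    pathway_sets: AnnotationCollection,
    background: set[str],
    ease: bool = False,
    david_style: bool = False,
) -> pd.DataFrame:
    """Pathway over-representation; ``ease`` applies the conservative
    k-1 variant, ``david_style`` adds the FDR column on the percentage
    scale (q x 100) familiar from DAVID-style reports."""
    table = _enrich(study, pathway_sets, background, ease=ease)
    if david_style and len(table):
        table["fdr_percent"] = table["q"] * 100.0
    return table


def build_go_map(significant_terms: set[str], dag: TermDag) -> nx.DiGraph:
    """Child->parent map restricted to significant terms.

    An edge (a, b) is kept iff b is an ancestor of a in the hierarchy and
    no other significant term lies on a path between them.
    """
    hierarchy = dag.to_digraph()  # edges child -> parent
    sig = set(significant_terms)
    reach = nx.DiGraph()
    reach.add_nodes_from(sig)
    for term in sig:
        if term not in hierarchy:
            continue
        ancestors = nx.descendants(hierarchy, term)  # follow child->parent arcs
        for anc in ancestors & sig:
            reach.add_edge(term, anc)
    return nx.transitive_reduction(reach)
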