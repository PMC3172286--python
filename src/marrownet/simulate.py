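"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates a five-timepoint (0, 3, 7, 11, 21 days) bone
marrow microarray experiment: per-gene baseline log2 intensities are
Normal(8, 1.5); non-differential genes stay flat up to additive
Normal(0, noise_sd) log2 noise per sample; each differential gene
follows one of the model temporal profiles (integer unit-change
trajectories) scaled by ``effect_log2``; genes of a planted module share
one trajectory, so their pairwise correlation is high. Values are
emitted on the intensity scale (2^log2), matching normalized array
output.

Companion generators plant an enriched annotation term, a PPI network
with a densified clique, a literature gene list with a controlled
overlap with the differential genes, and qPCR Ct tables at known fold
changes. Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    AnnotationCollection,
    ExpressionMatrix,
    TermDag,
    write_edge_list,
    write_expression,
    write_gene_list,
    write_gmt,
    write_term_dag,
)
from .profiles import ModelProfileSet, enumerate_candidate_profiles, select_model_profiles

__all__ = [
    "SimConfig",
    "TruthLabels",
    "simulate_timecourse",
    "simulate_annotations",
    "simulate_ppi_and_literature",
    "simulate_qpcr",
    "simulate_bundle",
]

log = logging.getLogger(__name__)

ROOT_TERM = "TERM:ROOT"
PLANTED_TERM = "TERM:0000"


@dataclass
class SimConfig:
    """Generator parameters; defaults mirror a 5-timepoint, 4-replicate
    recovery time-course with ~13% differential genes."""

    n_genes: int = 2000
    n_de: int = 260
    n_modules: int = 1
    module_size: int = 15
    timepoints: tuple[int, ...] = (0, 3, 7, 11, 21)
    n_replicates: int = 4
    noise_sd: float = 0.2
    effect_log2: float = 1.0
    seed: int = 0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_model_profiles: int = 50
    max_unit_change: int = 2

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if self.n_modules > 0 and self.module_size < 3:
            raise ValueError("module_size must be >= 3")
        if self.n_modules * self.module_size > self.n_de:
            raise ValueError("modules cannot cover more genes than n_de")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.effect_log2 <= 0:
            raise ValueError("effect_log2 must be positive")
        if 0 not in self.timepoints:
            raise ValueError("timepoints must include the baseline 0")


@dataclass
class TruthLabels:
    """Ground truth: which genes are differential, their temporal
    profile (step vector), module membership, and which annotation terms
    were planted as enriched."""

    de_genes: set[str]
    profile_of_gene: dict[str, tuple[int, ...]]
    module_of_gene: dict[str, int]
    enriched_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        stray = set(self.profile_of_gene) - self.de_genes
        if stray:
            raise ValueError(f"profiles assigned to non-differential genes: {sorted(stray)[:5]}")
        modules = sorted(set(self.module_of_gene.values()))
        if modules and modules != list(range(1, len(modules) + 1)):
            raise ValueError("module ids must be contiguous from 1")

    def module_genes(self, module_id: int) -> list[str]:
        return sorted(g for g, m in self.module_of_gene.items() if m == module_id)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": sorted(self.de_genes),
            "profile_of_gene": {g: list(s) for g, s in sorted(self.profile_of_gene.items())},
            "module_of_gene": dict(sorted(self.module_of_gene.items())),
            "enriched_terms": sorted(self.enriched_terms),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLabels":
        payload = json.loads(Path(path).read_text())
        return cls(
            de_genes=set(payload["de_genes"]),
            profile_of_gene={g: tuple(s) for g, s in payload["profile_of_gene"].items()},
            module_of_gene={g: int(m) for g, m in payload["module_of_gene"].items()},
            enriched_terms=set(payload["enriched_terms"]),
        )


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def model_profile_set(cfg: SimConfig) -> ModelProfileSet:
    candidates = enumerate_candidate_profiles(len(cfg.timepoints), cfg.max_unit_change)
    m = min(cfg.n_model_profiles, len(candidates))
    return select_model_profiles(candidates, m, seed=cfg.seed)


def simulate_timecourse(cfg: SimConfig) -> tuple[ExpressionMatrix, TruthLabels]:
    """Generate the expression matrix and its ground-truth labels.

    Differential genes take their step profile from the selected model
    profile set (so the clustering's "true profile" is well defined);
    module profiles are restricted to step vectors with sd >= 1 so a
    module carries usable temporal signal.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    tps = sorted(cfg.timepoints)

    pset = model_profile_set(cfg)
    steps = pset.steps_matrix()  # m x T
    step_sd = steps.std(axis=1)
    strong = np.flatnonzero(step_sd >= 1.0)
    if len(strong) < cfg.n_modules:
        strong = np.argsort(step_sd)[::-1][: max(cfg.n_modules, 1)]

    de_idx = rng.choice(cfg.n_genes, size=cfg.n_de, replace=False)
    de_genes = [genes[i] for i in sorted(de_idx)]

    module_of: dict[str, int] = {}
    profile_of: dict[str, tuple[int, ...]] = {}
    module_profile_rows = rng.choice(strong, size=cfg.n_modules, replace=len(strong) < cfg.n_modules)
    pool = list(de_genes)
    for mod in range(1, cfg.n_modules + 1):
        members, pool = pool[: cfg.module_size], pool[cfg.module_size:]
        row = int(module_profile_rows[mod - 1])
        for g in members:
            module_of[g] = mod
            profile_of[g] = tuple(int(s) for s in steps[row])
    free_rows = rng.integers(0, len(steps), size=len(pool))
    for g, row in zip(pool, free_rows):
        profile_of[g] = tuple(int(s) for s in steps[int(row)])

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    tp_index = {tp: j for j, tp in enumerate(tps)}
    signal = np.zeros((cfg.n_genes, len(tps)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, prof in profile_of.items():
        signal[gene_pos[g]] = cfg.effect_log2 * np.asarray(prof, dtype=float)

    columns, data = [], []
    for tp in tps:
        for rep in range(1, cfg.n_replicates + 1):
            columns.append(f"t{tp}_r{rep}")
            noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes) if cfg.noise_sd > 0 else 0.0
            data.append(baseline + signal[:, tp_index[tp]] + noise)
    log2_values = np.column_stack(data)
    values = pd.DataFrame(2.0 ** log2_values, index=pd.Index(genes, name="gene"), columns=columns)
    samples = pd.DataFrame(
        {
            "timepoint_days": [int(c.split("_")[0][1:]) for c in columns],
            "replicate": [int(c.split("_r")[1]) for c in columns],
            "group": ["baseline" if c.startswith("t0_") else "irradiated" for c in columns],
        },
        index=pd.Index(columns, name="sample_id"),
    )
    truth = TruthLabels(
        de_genes=set(de_genes), profile_of_gene=profile_of, module_of_gene=module_of
    )
    return ExpressionMatrix(values, samples), truth


def simulate_annotations(
    truth: TruthLabels,
    universe: list[str],
    seed: int = 0,
    n_background_terms: int = 20,
    background_term_size: int = 30,
    planted_term_size: int = 50,
    planted_de_members: int = 40,
    namespace: str = "synthetic_go",
) -> tuple[AnnotationCollection, TermDag, TruthLabels]:
    """Plant one term concentrated in the differential genes among
    uniformly drawn background terms; the DAG hangs every term under a
    root term that contains the whole universe."""
    rng = np.random.default_rng(seed)
    universe = [g.upper() for g in universe]
    de = sorted(g.upper() for g in truth.de_genes)
    non_de = sorted(set(universe) - set(de))

    module_members = sorted({g.upper() for g in truth.module_of_gene})
    n_de_members = max(planted_de_members, len(module_members))
    extra_de = [g for g in de if g not in module_members]
    rng.shuffle(extra_de)
    de_members = module_members + extra_de[: n_de_members - len(module_members)]
    filler = list(rng.choice(non_de, size=max(planted_term_size - len(de_members), 0), replace=False))
    planted = frozenset(de_members + filler)

    terms: dict[str, tuple[str, frozenset[str]]] = {
        PLANTED_TERM: ("planted differential-response term", planted),
        ROOT_TERM: ("root", frozenset(universe)),
    }
    for i in range(1, n_background_terms + 1):
        members = rng.choice(universe, size=background_term_size, replace=False)
        terms[f"TERM:{i:04d}"] = (f"background term {i}", frozenset(members))
    collection = AnnotationCollection(terms, namespace=namespace)
    dag = TermDag(frozenset((t, ROOT_TERM) for t in terms if t != ROOT_TERM))
    truth.enriched_terms.add(PLANTED_TERM)
    return collection, dag, truth


def simulate_ppi_and_literature(
    truth: TruthLabels,
    universe: list[str],
    seed: int = 0,
    literature_size: int = 514,
    overlap_k: int = 42,
    n_external: int = 300,
    edge_prob: float = 0.015,
    clique_size: int = 12,
) -> tuple[nx.Graph, list[str]]:
    """Random PPI over the literature symbols with a densified clique on
    the first ``clique_size`` overlap genes; the literature list overlaps
    the differential genes by exactly ``overlap_k`` symbols."""
    rng = np.random.default_rng(seed)
    universe = [g.upper() for g in universe]
    de = sorted(g.upper() for g in truth.de_genes)
    if overlap_k > len(de):
        raise ValueError("overlap_k exceeds the number of differential genes")
    overlap = list(rng.choice(de, size=overlap_k, replace=False)) if overlap_k else []
    non_de = sorted(set(universe) - set(de))
    external = [f"EXT{i:04d}" for i in range(n_external)]
    filler_pool = non_de + external
    n_filler = literature_size - overlap_k
    filler = list(rng.choice(filler_pool, size=n_filler, replace=False))
    literature = sorted(overlap) + sorted(filler)

    graph = nx.Graph()
    graph.add_nodes_from(literature)
    nodes = list(literature)
    n = len(nodes)
    upper = rng.random((n, n)) < edge_prob
    for i in range(n):
        for j in range(i + 1, n):
            if upper[i, j]:
                graph.add_edge(nodes[i], nodes[j])
    clique = sorted(overlap)[: min(clique_size, len(overlap))]
    for i, a in enumerate(clique):
        for b in clique[i + 1 :]:
            graph.add_edge(a, b)
    graph.remove_edges_from(nx.selfloop_edges(graph))
    return graph, literature


def simulate_qpcr(
    fold_changes: dict[tuple[str, int], float],
    seed: int = 0,
    n_replicates: int = 3,
    noise_sd: float = 0.1,
    reference_ct: float = 20.0,
    target_ct: float = 25.0,
) -> pd.DataFrame:
    """Ct table realizing the given (gene, timepoint) -> fold truths.

    The reference gene sits at a constant Ct (plus noise); the treated
    target Ct is the control target Ct minus log2(fold). Three
    replicates per condition by default.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def noise() -> float:
        return float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0

    genes = sorted({g for g, _ in fold_changes})
    for gene in genes:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "gene": gene,
                    "timepoint_days": 0,
                    "condition": "control",
                    "replicate": rep,
                    "ct_target": target_ct + noise(),
                    "ct_reference": reference_ct + noise(),
                }
            )
    for (gene, tp), fold in sorted(fold_changes.items()):
        if fold <= 0:
            raise ValueError(f"fold must be positive, got {fold} for {gene}")
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "gene": gene,
                    "timepoint_days": int(tp),
                    "condition": "treated",
                    "replicate": rep,
                    "ct_target": target_ct - float(np.log2(fold)) + noise(),
                    "ct_reference": reference_ct + noise(),
                }
            )
    return pd.DataFrame(rows)


def simulate_bundle(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic input bundle (expression TSV, GMT, DAG
    TSV, PPI TSV, literature list, Ct TSV, truth JSON) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_timecourse(cfg)
    annotations, dag, truth = simulate_annotations(truth, matrix.genes, seed=cfg.seed + 1)
    # scale the literature list down for small simulations so the filler
    # pool (non-differential + external symbols) can always cover it
    overlap_k = min(42, cfg.n_de)
    pool = (cfg.n_genes - cfg.n_de) + 300
    literature_size = min(514, overlap_k + pool)
    ppi, literature = simulate_ppi_and_literature(
        truth, matrix.genes, seed=cfg.seed + 2,
        literature_size=literature_size, overlap_k=overlap_k,
    )

    rng = np.random.default_rng(cfg.seed + 3)
    qpcr_genes = sorted(rng.choice(sorted(truth.de_genes), size=min(6, len(truth.de_genes)), replace=False))
    tps = [t for t in sorted(cfg.timepoints) if t != 0]
    # validate only where the planted profile actually moves: a fold of
    # exactly 1 has no direction to confirm
    folds = {
        (g, tp): float(2.0 ** (cfg.effect_log2 * truth.profile_of_gene[g][i + 1]))
        for g in qpcr_genes
        for i, tp in enumerate(tps)
        if truth.profile_of_gene[g][i + 1] != 0
    }
    ct = simulate_qpcr(folds, seed=cfg.seed + 4)

    paths = {
        "expression": out / "expression.tsv",
        "gmt": out / "annotations.gmt",
        "dag": out / "term_dag.tsv",
        "ppi": out / "ppi_edges.tsv",
        "literature": out / "literature_genes.txt",
        "ct": out / "qpcr_ct.tsv",
        "truth": out / "truth.json",
    }
    write_expression(matrix, paths["expression"])
    write_gmt(annotations, paths["gmt"])
    write_term_dag(dag, paths["dag"])
    write_edge_list(ppi, paths["ppi"])
    write_gene_list(literature, paths["literature"])
    ct.to_csv(paths["ct"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    log.info("synthetic bundle written to %s", out)
    return paths
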