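"""Readers and writers for the external formats the pipeline touches.

Formats are all plain text: expression matrices and edge lists as TSV,
gene sets as GMT, the term DAG as a two-column child/parent TSV, gene
lists as one symbol per line, and qPCR Ct tables as tidy TSV.

Sample identity is carried either by a metadata sidecar TSV
(``sample_id  timepoint_days  replicate  group``) or, absent one, by the
column-name convention ``t{days}_r{replicate}`` (``t0_r1`` is a baseline
chip). Cross-list gene comparisons elsewhere in the package are done on
uppercased symbols, so symbol-list readers uppercase on input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "ExpressionMatrix",
    "AnnotationCollection",
    "TermDag",
    "read_expression",
    "write_expression",
    "read_sample_metadata",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_term_dag",
    "write_term_dag",
    "read_gene_list",
    "write_gene_list",
    "read_ct_table",
]

_SAMPLE_ID_RE = re.compile(r"^t(\d+)_r(\d+)$")

BASELINE = "baseline"
IRRADIATED = "irradiated"


@dataclass(frozen=True)
class SampleMeta:
    """One chip: its timepoint (days), replicate number and group."""

    sample_id: str
    timepoint_days: int
    replicate: int
    group: str

    def __post_init__(self) -> None:
        if self.timepoint_days < 0:
            raise ValueError(f"negative timepoint for sample {self.sample_id!r}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1 for sample {self.sample_id!r}")
        if self.group not in (BASELINE, IRRADIATED):
            raise ValueError(
                f"group must be '{BASELINE}' or '{IRRADIATED}', "
                f"got {self.group!r} for {self.sample_id!r}"
            )


def parse_sample_id(sample_id: str) -> SampleMeta:
    """Parse the ``t{days}_r{rep}`` header convention.

    Under this convention timepoint 0 and the baseline group coincide.
    """
    m = _SAMPLE_ID_RE.match(sample_id)
    if m is None:
        raise ValueError(
            f"sample id {sample_id!r} does not follow the t{{days}}_r{{rep}} "
            "convention; provide a metadata sidecar instead"
        )
    days, rep = int(m.group(1)), int(m.group(2))
    group = BASELINE if days == 0 else IRRADIATED
    return SampleMeta(sample_id, days, rep, group)


@dataclass
class ExpressionMatrix:
    """Normalized intensities (genes x samples) plus sample metadata.

    ``values`` holds intensity-scale numbers; analyses log2-transform.
    ``samples`` is indexed by sample_id with columns timepoint_days,
    replicate and group, in the column order of ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene symbol: {dup!r}")
        if self.values.isna().any().any():
            gene = self.values.index[self.values.isna().any(axis=1)][0]
            raise ValueError(f"missing value in row for gene {gene!r}")
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        extra = [s for s in self.samples.index if s not in self.values.columns]
        if extra:
            raise ValueError(f"metadata for absent samples: {extra}")
        self.samples = self.samples.loc[list(self.values.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.samples["timepoint_days"].unique())

    def samples_at(self, timepoint_days: int) -> list[str]:
        mask = self.samples["timepoint_days"] == timepoint_days
        return list(self.samples.index[mask])

    def baseline_samples(self, pooled: bool = False) -> list[str]:
        """Baseline chip ids; ``pooled`` takes every group=='baseline' chip
        regardless of the timepoint it was hybridized alongside."""
        if pooled:
            return list(self.samples.index[self.samples["group"] == BASELINE])
        return self.samples_at(0)

    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], self.samples.copy())


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "timepoint_days", "replicate", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata sidecar missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata sidecar")
    for row in meta.itertuples(index=False):
        SampleMeta(row.sample_id, int(row.timepoint_days), int(row.replicate), row.group)
    return meta.set_index("sample_id")[["timepoint_days", "replicate", "group"]]


def read_expression(
    path: str | Path, metadata: str | Path | pd.DataFrame | None = None
) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene symbol).

    Sample metadata comes from ``metadata`` (sidecar path or frame) or is
    parsed from the ``t{days}_r{rep}`` column names. Duplicate gene rows,
    missing and non-numeric cells are rejected with the offending
    row/column named.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene symbol in {path}: {dup!r}")
    values = pd.DataFrame(index=raw.index.astype(str))
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad][0]
            raise ValueError(
                f"non-numeric value {raw.loc[gene, col]!r} at gene {gene!r}, "
                f"sample {col!r} in {path}"
            )
        if converted.isna().any():
            gene = raw.index[converted.isna()][0]
            raise ValueError(f"missing value at gene {gene!r}, sample {col!r} in {path}")
        values[col] = converted.to_numpy(dtype=float)

    if metadata is None:
        metas = [parse_sample_id(c) for c in values.columns]
        samples = pd.DataFrame(
            {
                "timepoint_days": [m.timepoint_days for m in metas],
                "replicate": [m.replicate for m in metas],
                "group": [m.group for m in metas],
            },
            index=pd.Index(values.columns, name="sample_id"),
        )
    elif isinstance(metadata, pd.DataFrame):
        samples = metadata
    else:
        samples = read_sample_metadata(metadata)
    return ExpressionMatrix(values, samples)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


@dataclass
class AnnotationCollection:
    """Named gene sets (GO terms, pathways): term_id -> (name, genes)."""

    terms: dict[str, tuple[str, frozenset[str]]]
    namespace: str = ""

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {term_id!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.terms)

    def genes_of(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def name_of(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return frozenset(out)


def read_gmt(path: str | Path, namespace: str = "") -> AnnotationCollection:
    """Read a GMT file: ``term_id <tab> description <tab> gene...`` per line.

    Genes are uppercased and de-duplicated within a line.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3")
        term_id, name = fields[0], fields[1]
        if term_id in terms:
            raise ValueError(f"{path}:{lineno}: duplicate term id {term_id!r}")
        genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
        if not genes:
            raise ValueError(f"{path}:{lineno}: term {term_id!r} has no genes")
        terms[term_id] = (name, genes)
    return AnnotationCollection(terms, namespace=namespace)


def write_gmt(collection: AnnotationCollection, path: str | Path) -> None:
    lines = []
    for term_id in sorted(collection.terms):
        name, genes = collection.terms[term_id]
        lines.append("\t".join([term_id, name, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an undirected PPI edge list (two whitespace-separated symbols
    per line). Symbols are uppercased; self-loops dropped; duplicate edges
    in either orientation collapsed."""
    graph = nx.Graph()
    n_lines = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two symbols, got {raw!r}")
        a, b = parts[0].upper(), parts[1].upper()
        n_lines += 1
        if a == b:
            continue
        graph.add_edge(a, b)
    if n_lines == 0:
        raise ValueError(f"empty edge list: {path}")
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    lines = [f"{min(a, b)}\t{max(a, b)}" for a, b in graph.edges()]
    Path(path).write_text("\n".join(sorted(lines)) + ("\n" if lines else ""))


@dataclass
class TermDag:
    """Child -> parent subsumption edges between annotation terms."""

    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        g = self.to_digraph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"term hierarchy contains a cycle: {cycle}")

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        return g

    def validate_terms(self, collection: AnnotationCollection) -> None:
        known = set(collection.terms)
        unknown = {t for edge in self.edges for t in edge} - known
        if unknown:
            raise ValueError(f"DAG references unknown terms: {sorted(unknown)}")


def read_term_dag(path: str | Path) -> TermDag:
    edges: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'child<TAB>parent', got {raw!r}")
        edges.add((parts[0], parts[1]))
    return TermDag(frozenset(edges))


def write_term_dag(dag: TermDag, path: str | Path) -> None:
    lines = sorted(f"{c}\t{p}" for c, p in dag.edges)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line, uppercased, order kept, duplicates collapsed."""
    seen: dict[str, None] = {}
    for raw in Path(path).read_text().splitlines():
        sym = raw.strip().upper()
        if sym and not sym.startswith("#"):
            seen.setdefault(sym, None)
    return list(seen)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


CT_COLUMNS = ["gene", "timepoint_days", "condition", "replicate", "ct_target", "ct_reference"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Tidy qPCR Ct table; Ct values must lie in the instrument range (0, 45)."""
    table = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    for col in ("ct_target", "ct_reference"):
        bad = ~table[col].between(0, 45, inclusive="neither")
        if bad.any():
            row = table[bad].iloc[0]
            raise ValueError(
                f"Ct value {row[col]} out of range (0, 45) for gene {row['gene']!r}"
            )
    return table
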