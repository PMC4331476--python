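"""Readers and writers for the plain-text formats the pipeline touches.

Gene sets travel as GMT, pathway topology as two/three-column SIF-style
edge lists, expression as TSV with a sample-group sidecar, miRNA loci as
BED, and run configuration as YAML/JSON.  All genomic coordinates are
stored 0-based half-open internally; gene symbols are case-insensitive
and stored uppercase, while miRNA identifiers keep their canonical
lowercase ``hsa-...`` form and live in a separate namespace.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

logger = logging.getLogger("mircross")

__all__ = [
    "GeneSet",
    "PathwayGraph",
    "GenomicInterval",
    "RunConfig",
    "ParseError",
    "read_gmt",
    "write_gmt",
    "read_pathway_graph",
    "write_pathway_graph",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_groups",
    "write_groups",
    "read_bed",
    "write_bed",
    "read_predictions",
    "write_predictions",
    "load_config",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (uppercase strings)."""

    set_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} is empty")


@dataclass
class PathwayGraph:
    """Undirected simple graph over a pathway's gene symbols."""

    pathway_id: str
    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"{self.feature_id}: bad strand {self.strand!r}")


@dataclass
class RunConfig:
    """Thresholds and sizes steering every pipeline stage.

    Defaults are the screening constants used throughout: fold change
    > 2, SAM FDR < 0.05, enrichment P < 0.05, GO FDR < 0.05, crosstalk
    P < 0.05, >= 4 supporting prediction tools, k = 4 for subpathway
    mining, and a 10 kb genomic cluster gap.
    """

    fc_cutoff: float = 2.0
    de_fdr: float = 0.05
    enrich_p: float = 0.05
    go_fdr: float = 0.05
    crosstalk_p: float = 0.05
    consensus_min_tools: int = 4
    lap_k: int = 4
    cluster_gap_bp: int = 10_000
    background_size: int | str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fc_cutoff", "de_fdr", "enrich_p", "go_fdr",
                     "crosstalk_p", "lap_k", "cluster_gap_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.consensus_min_tools < 1:
            raise ValueError("consensus_min_tools must be >= 1")
        if self.background_size != "auto" and int(self.background_size) <= 0:
            raise ValueError("background_size must be 'auto' or a positive int")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one tab-separated ``id<TAB>description<TAB>genes...``
    line per set.  Symbols are uppercased and deduplicated."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            set_id, name, *genes = fields
            symbols = frozenset(g.strip().upper() for g in genes if g.strip())
            if not symbols:
                raise ParseError(f"{path}:{lineno}: gene set {set_id!r} is empty")
            sets.append(GeneSet(set_id=set_id, name=name, genes=symbols))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Pathway topology (SIF-style edge list)
# ---------------------------------------------------------------------------

def read_pathway_graph(path: str | Path, pathway_id: str | None = None) -> PathwayGraph:
    """Read an undirected simple graph from a 2/3-column edge list.

    A one-column line declares an isolated node.  In three-column SIF
    order (source, relation, target) the middle column is ignored.
    Self-loop lines are skipped with a warning.
    """
    g = nx.Graph()
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip().upper() for f in line.split("\t") if f.strip()]
            if len(fields) == 1:
                g.add_node(fields[0])
                continue
            a, b = (fields[0], fields[2]) if len(fields) >= 3 else (fields[0], fields[1])
            if a == b:
                logger.warning("%s:%d: self-loop on %s skipped", path, lineno, a)
                g.add_node(a)
                continue
            g.add_edge(a, b)
    return PathwayGraph(pathway_id=pathway_id or path.stem, graph=g)


def write_pathway_graph(pg: PathwayGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in pg.graph.edges):
            fh.write(f"{a}\t{b}\n")
        for n in sorted(nx.isolates(pg.graph)):
            fh.write(f"{n}\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_groups(path: str | Path) -> dict[str, str]:
    """Read the two-column sample-to-group TSV (sample, case|control)."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.lower().startswith("sample\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in {"case", "control"}:
                raise ParseError(
                    f"{path}:{lineno}: expected 'sample<TAB>case|control'"
                )
            groups[parts[0]] = parts[1]
    return groups


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for s, g in groups.items():
            fh.write(f"{s}\t{g}\n")


def read_expression_tsv(path: str | Path, group_file: str | Path):
    """Read a features x samples TSV plus its group sidecar.

    Returns an :class:`mircross.de.ExpressionMatrix`.  Every sample in the
    header must be mapped by the group file; duplicate feature ids and
    non-numeric cells are errors.
    """
    from .de import ExpressionMatrix  # local import: avoid cycle

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated feature id(s): {dups}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression cell: {exc}") from exc
    groups = read_groups(group_file)
    missing = [s for s in values.columns if s not in groups]
    if missing:
        raise ParseError(f"{group_file}: samples missing from group file: {missing}")
    return ExpressionMatrix(values=values, group={s: groups[s] for s in values.columns})


def write_expression_tsv(matrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature")


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (>=4 columns); strand from column 6 when present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: BED needs >=4 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = f[5] if len(f) >= 6 else "."
            # tolerate the unicode minus some exports emit
            strand = {"−": "-"}.get(strand, strand)
            try:
                out.append(GenomicInterval(f[3], f[0], start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.feature_id}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Prediction tables
# ---------------------------------------------------------------------------

def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read the (mirna, gene, tool) prediction TSV; gene symbols uppercased."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mirna", "gene", "tool"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: columns must include {sorted(required)}")
    df["gene"] = df["gene"].str.upper()
    return df


def write_predictions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON config, falling back to defaults for absent keys."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
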