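"""k-clique mining of local areas of pathways (LAPs).

A pathway is rarely disrupted globally; the disrupted part is a local
neighborhood.  Given a pathway graph and a set of *signature* genes
(by default key-gene candidates: DE genes that are consensus targets of
inversely DE miRNAs), a LAP is a maximal set of signature genes that are
pairwise close in the graph — distance < k with the strict convention
(default k = 4, so pairwise shortest-path distance <= 3), or <= k with
``strict=False``.  Mining builds an auxiliary graph joining signature
pairs that meet the distance constraint and enumerates its maximal
cliques (Bron-Kerbosch via networkx); non-signature genes on shortest
paths between a LAP's signature genes are added as linkers for context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import networkx as nx

from .de import DERecord
from .enrichment import hypergeom_upper_tail
from .io_formats import PathwayGraph
from .targets import ConsensusTargetMap

logger = logging.getLogger("mircross")

__all__ = ["LAPConfig", "LAP", "signature_genes", "mine_laps", "lap_enrichment"]


@dataclass
class LAPConfig:
    k: int = 4
    strict: bool = True  # True: distance < k; False: distance <= k
    min_signature: int = 2
    include_linkers: bool = True

    def __post_init__(self) -> None:
        if self.k < 1 or self.min_signature < 1:
            raise ValueError("k and min_signature must be >= 1")


@dataclass
class LAP:
    lap_id: str
    pathway_id: str
    signature_genes: frozenset[str]
    linker_genes: frozenset[str]
    subgraph: nx.Graph
    enrichment_p: float = float("nan")

    @property
    def genes(self) -> frozenset[str]:
        return self.signature_genes | self.linker_genes


def signature_genes(
    pathway_graph: PathwayGraph,
    de_mrnas_up: Sequence[DERecord],
    de_mrnas_down: Sequence[DERecord],
    consensus_map: ConsensusTargetMap,
    de_mirnas_up: Sequence[DERecord],
    de_mirnas_down: Sequence[DERecord],
    mode: str = "key",
) -> set[str]:
    """Pathway nodes qualifying as LAP signature genes.

    ``key`` (default): DE nodes that are consensus targets of an
    inversely DE miRNA.  ``targets``: consensus targets of any DE miRNA.
    ``de``: DE nodes.
    """
    nodes = pathway_graph.nodes
    gene_dir = {r.feature_id: "up" for r in de_mrnas_up}
    gene_dir.update({r.feature_id: "down" for r in de_mrnas_down})
    mirna_dir = {r.feature_id: "up" for r in de_mirnas_up}
    mirna_dir.update({r.feature_id: "down" for r in de_mirnas_down})
    targeted_by: dict[str, set[str]] = {}
    for mirna, genes in consensus_map.targets.items():
        if mirna not in mirna_dir:
            continue
        for g in genes:
            targeted_by.setdefault(g, set()).add(mirna)

    if mode == "de":
        return {g for g in nodes if g in gene_dir}
    if mode == "targets":
        return {g for g in nodes if targeted_by.get(g)}
    if mode != "key":
        raise ValueError(f"unknown signature mode {mode!r}")
    out = set()
    for g in nodes:
        if g not in gene_dir:
            continue
        if any(mirna_dir[m] != gene_dir[g] for m in targeted_by.get(g, ())):
            out.add(g)
    return out


def _distance_ok(dist: float, config: LAPConfig) -> bool:
    return dist < config.k if config.strict else dist <= config.k


def mine_laps(
    pathway_graph: PathwayGraph, signature: set[str], config: LAPConfig | None = None
) -> list[LAP]:
    """Maximal pairwise-close signature sets of one pathway graph.

    Signature pairs at infinite distance (disconnected) never share a
    LAP.  Output is sorted by lexicographically smallest signature set
    and numbered ``<pathway>_<i>``.
    """
    config = config or LAPConfig()
    g = pathway_graph.graph.to_undirected() if pathway_graph.graph.is_directed() else pathway_graph.graph
    missing = signature - set(g.nodes)
    if missing:
        raise ValueError(f"signature genes not in graph: {sorted(missing)}")
    sig = sorted(signature)
    # pairwise shortest-path distances among signature genes
    dist: dict[str, dict[str, int]] = {
        s: nx.single_source_shortest_path_length(g, s) for s in sig
    }
    aux = nx.Graph()
    aux.add_nodes_from(sig)
    for a, b in combinations(sig, 2):
        if b in dist[a] and _distance_ok(dist[a][b], config):
            aux.add_edge(a, b)
    laps: list[LAP] = []
    cliques = [
        frozenset(c) for c in nx.find_cliques(aux) if len(c) >= config.min_signature
    ]
    for clique in sorted(cliques, key=lambda c: sorted(c)):
        linkers: set[str] = set()
        if config.include_linkers:
            for a, b in combinations(sorted(clique), 2):
                for path in nx.all_shortest_paths(g, a, b):
                    linkers.update(path)
            linkers -= clique
        sub = g.subgraph(clique | linkers).copy()
        laps.append(
            LAP(
                lap_id=f"{pathway_graph.pathway_id}_{len(laps) + 1}",
                pathway_id=pathway_graph.pathway_id,
                signature_genes=clique,
                linker_genes=frozenset(linkers),
                subgraph=sub,
            )
        )
    return laps


def lap_enrichment(
    laps: Sequence[LAP], query_genes, background, alpha: float = 0.05
) -> list[LAP]:
    """Hypergeometric enrichment of the query in each LAP's gene set."""
    background = frozenset(g.upper() for g in background)
    query = {g.upper() for g in query_genes} & background
    out = []
    for lap in laps:
        members = lap.genes & background
        x = len(query & members)
        p = hypergeom_upper_tail(x, len(background), len(query), len(members))
        out.append(
            LAP(
                lap_id=lap.lap_id,
                pathway_id=lap.pathway_id,
                signature_genes=lap.signature_genes,
                linker_genes=lap.linker_genes,
                subgraph=lap.subgraph,
                enrichment_p=p,
            )
        )
    return out
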