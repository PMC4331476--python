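"""Pathway crosstalk, hierarchical clustering, key genes and mediation.

Crosstalk between two pathways is the cumulative hypergeometric tail of
their gene-set overlap against the genome-wide background: with N
background genes, pathway sizes n and m and overlap x, small tail
probabilities mean the pathways share more genes than chance.  The
-log10 P values over all pairs form a symmetric crosstalk matrix that
is grouped by agglomerative clustering (complete linkage on Euclidean
row distances).  Key genes are DE pathway members that are consensus
targets of an inversely DE miRNA; those sitting in two or more
dysregulated pathways are mediators, and the mediation fraction of a
gene subset is the share of significant crosstalk pairs whose shared
genes it intersects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .de import DERecord
from .enrichment import TailMode, hypergeom_upper_tail
from .integration import DysregulatedPathway
from .io_formats import GeneSet
from .targets import ConsensusTargetMap

logger = logging.getLogger("mircross")

P_FLOOR = 1e-300  # floor before -log10 so the matrix stays finite

__all__ = [
    "CrosstalkPair",
    "CrosstalkMatrix",
    "KeyGene",
    "crosstalk_all_pairs",
    "cluster_crosstalk",
    "detect_key_genes",
    "mediation_fraction",
    "linkage_to_newick",
]


@dataclass(frozen=True)
class CrosstalkPair:
    pathway_a: str
    pathway_b: str
    N: int
    n: int
    m: int
    x: int
    p_value: float
    shared_genes: frozenset[str]
    significant: bool

    def __post_init__(self) -> None:
        if self.pathway_a == self.pathway_b:
            raise ValueError("crosstalk pair must join two distinct pathways")
        if len(self.shared_genes) != self.x:
            raise ValueError("shared gene list inconsistent with x")


@dataclass
class CrosstalkMatrix:
    pathway_ids: list[str]
    neg_log10_p: pd.DataFrame  # symmetric, zero diagonal
    linkage_matrix: np.ndarray
    cluster_labels: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return self.neg_log10_p


@dataclass(frozen=True)
class KeyGene:
    gene: str
    direction: str
    pathways: frozenset[str]
    regulating_mirnas: frozenset[str]
    is_mediator: bool


def crosstalk_all_pairs(
    pathways: Sequence[GeneSet],
    background,
    alpha: float = 0.05,
    mode: TailMode = "at_least",
    restrict_to: Iterable[str] | None = None,
) -> list[CrosstalkPair]:
    """Hypergeometric overlap test for every unordered pathway pair.

    ``restrict_to`` optionally intersects each pathway's gene set with a
    gene list (e.g. DE genes) before testing — a sensitivity-analysis
    variant; the default tests full pathway memberships.
    """
    if len(pathways) < 2:
        raise ValueError("need >= 2 pathways for crosstalk")
    background = frozenset(background)
    restrict = frozenset(g.upper() for g in restrict_to) if restrict_to is not None else None
    members: dict[str, frozenset[str]] = {}
    for gs in pathways:
        genes = gs.genes & background
        if restrict is not None:
            genes &= restrict
        members[gs.set_id] = frozenset(genes)
    N = len(background)
    ids = sorted(members)
    pairs: list[CrosstalkPair] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            shared = members[a] & members[b]
            p = hypergeom_upper_tail(
                len(shared), N, len(members[a]), len(members[b]), mode
            )
            pairs.append(
                CrosstalkPair(
                    pathway_a=a, pathway_b=b, N=N,
                    n=len(members[a]), m=len(members[b]), x=len(shared),
                    p_value=p, shared_genes=shared, significant=p < alpha,
                )
            )
    return pairs


def cluster_crosstalk(
    pairs: Sequence[CrosstalkPair],
    n_clusters: int | None = None,
    cut_height: float | None = None,
    method: str = "complete",
) -> CrosstalkMatrix:
    """Cluster pathways on the -log10 P crosstalk matrix.

    Rows of the symmetric matrix are compared by Euclidean distance and
    merged agglomeratively (complete linkage by default; scipy's
    deterministic lowest-index tie-breaking).  Flat clusters come from
    ``n_clusters`` or ``cut_height``; when neither is given the tree is
    cut in the middle of the largest gap between successive merge
    heights, which separates tight blocks from the loose top-level
    merges.
    """
    ids = sorted({p.pathway_a for p in pairs} | {p.pathway_b for p in pairs})
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for p in pairs:
        v = -np.log10(max(p.p_value, P_FLOOR))
        mat.loc[p.pathway_a, p.pathway_b] = v
        mat.loc[p.pathway_b, p.pathway_a] = v
    if np.allclose(mat.to_numpy(), 0.0):
        logger.warning("all crosstalk p = 1; single cluster")
        labels = {pid: 1 for pid in ids}
        Z = linkage(np.zeros((len(ids), 1)), method=method)
        return CrosstalkMatrix(ids, mat, Z, labels)
    # pairwise Euclidean distances between matrix rows
    from scipy.spatial.distance import pdist

    Z = linkage(pdist(mat.to_numpy(), metric="euclidean"), method=method)
    if n_clusters is not None:
        flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        height = cut_height if cut_height is not None else _gap_cut(Z[:, 2])
        flat = fcluster(Z, t=height, criterion="distance")
    return CrosstalkMatrix(ids, mat, Z, dict(zip(ids, (int(c) for c in flat))))


def _gap_cut(heights: np.ndarray) -> float:
    """Cut height at the midpoint of the largest merge-height gap."""
    h = np.sort(np.asarray(heights, dtype=float))
    if len(h) < 2 or h[-1] - h[0] < 1e-12:
        return h[-1] + 1.0  # no structure: one cluster
    gaps = np.diff(h)
    i = int(np.argmax(gaps))
    return float((h[i] + h[i + 1]) / 2.0)


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    trees = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        trees[n + k] = f"({trees[a]}:{la:.6g},{trees[b]}:{lb:.6g})"
        heights[n + k] = h
    return trees[n + len(Z) - 1] + ";"


def detect_key_genes(
    dysregulated: Sequence[DysregulatedPathway],
    collection: Sequence[GeneSet],
    consensus_map: ConsensusTargetMap,
    de_mrnas_up: Sequence[DERecord],
    de_mrnas_down: Sequence[DERecord],
    de_mirnas_up: Sequence[DERecord],
    de_mirnas_down: Sequence[DERecord],
) -> list[KeyGene]:
    """Genes that are DE, sit in a dysregulated pathway, and are consensus
    targets of at least one inversely DE miRNA; mediators span >= 2 pathways."""
    by_id = {gs.set_id: gs for gs in collection}
    gene_dir = {r.feature_id: "up" for r in de_mrnas_up}
    gene_dir.update({r.feature_id: "down" for r in de_mrnas_down})
    mirna_dir = {r.feature_id: "up" for r in de_mirnas_up}
    mirna_dir.update({r.feature_id: "down" for r in de_mirnas_down})
    # invert the consensus map once: gene -> DE miRNAs targeting it
    targeted_by: dict[str, set[str]] = {}
    for mirna, genes in consensus_map.targets.items():
        if mirna not in mirna_dir:
            continue
        for g in genes:
            targeted_by.setdefault(g, set()).add(mirna)

    membership: dict[str, set[str]] = {}
    for dp in dysregulated:
        gs = by_id.get(dp.pathway_id)
        if gs is None:
            raise ValueError(f"pathway {dp.pathway_id} not in collection")
        for g in gs.genes:
            membership.setdefault(g, set()).add(dp.pathway_id)

    out: list[KeyGene] = []
    for gene in sorted(membership):
        if gene not in gene_dir:
            continue  # not DE
        inverse = {
            m for m in targeted_by.get(gene, ())
            if mirna_dir[m] != gene_dir[gene]
        }
        if not inverse:
            continue
        out.append(
            KeyGene(
                gene=gene,
                direction=gene_dir[gene],
                pathways=frozenset(membership[gene]),
                regulating_mirnas=frozenset(inverse),
                is_mediator=len(membership[gene]) >= 2,
            )
        )
    return out


def mediation_fraction(
    significant_pairs: Sequence[CrosstalkPair], gene_subset: Iterable[str]
) -> float:
    """Fraction of significant crosstalk pairs whose shared genes hit the subset."""
    sig = [p for p in significant_pairs if p.significant]
    if not sig:
        raise ValueError("no significant crosstalk pairs")
    subset = {g.upper() for g in gene_subset}
    mediated = sum(1 for p in sig if p.shared_genes & subset)
    return mediated / len(sig)
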