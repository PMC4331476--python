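"""Genomic clustering of miRNA genes and cluster-level pathway coregulation.

miRNA genes transcribed from one polycistron lie close together on the
chromosome; a cluster here chains miRNA loci on the same chromosome
whose consecutive end-to-start gaps are at most 10 kb (single linkage,
so a cluster may span more than 10 kb overall).  Clusters whose members
regulate the same pathway suggest synergistic regulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .io_formats import GenomicInterval

logger = logging.getLogger("mircross")

__all__ = ["MiRNACluster", "cluster_mirnas", "cluster_pathway_coregulation"]


@dataclass
class MiRNACluster:
    cluster_id: str
    chrom: str
    members: list[GenomicInterval]  # sorted by start
    coregulated_pathways: set[str] = field(default_factory=set)

    @property
    def span(self) -> int:
        return self.members[-1].end - self.members[0].start

    @property
    def member_ids(self) -> list[str]:
        return [m.feature_id for m in self.members]


def cluster_mirnas(
    intervals: Sequence[GenomicInterval], gap_bp: int = 10_000
) -> list[MiRNACluster]:
    """Chain same-chromosome miRNA loci with consecutive gaps <= gap_bp.

    Gap = next.start - current.end between start-sorted neighbors;
    overlapping loci (non-positive gap) always co-cluster.  Singletons
    are reported as size-1 clusters.  Strand is ignored.
    """
    if gap_bp <= 0:
        raise ValueError("gap_bp must be > 0")
    ids = [iv.feature_id for iv in intervals]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate miRNA id(s): {dup}")
    clusters: list[MiRNACluster] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        loci = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end, iv.feature_id))
        current = [loci[0]]
        rightmost = loci[0].end
        for iv in loci[1:]:
            if iv.start - rightmost <= gap_bp:
                current.append(iv)
            else:
                clusters.append(
                    MiRNACluster(f"{chrom}:{current[0].start}", chrom, current)
                )
                current = [iv]
            rightmost = max(rightmost, iv.end)
        clusters.append(MiRNACluster(f"{chrom}:{current[0].start}", chrom, current))
    return clusters


def cluster_pathway_coregulation(
    clusters: Sequence[MiRNACluster], edges: pd.DataFrame
) -> list[MiRNACluster]:
    """Attach pathways regulated by >= 2 distinct members of each cluster.

    ``edges`` is the miRNA-pathway table from the integration stage
    (columns mirna, pathway).  Size-1 clusters get an empty set.
    """
    pathway_regulators: dict[str, set[str]] = {}
    for _, row in edges.iterrows():
        pathway_regulators.setdefault(row["pathway"], set()).add(row["mirna"])
    out = []
    for c in clusters:
        coreg: set[str] = set()
        if len(c.members) >= 2:
            member_ids = set(c.member_ids)
            for pathway, regulators in pathway_regulators.items():
                if len(regulators & member_ids) >= 2:
                    coreg.add(pathway)
        out.append(
            MiRNACluster(c.cluster_id, c.chrom, list(c.members), coreg)
        )
    return out
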