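"""Inverse-regulation integration of DE mRNAs, DE miRNAs and pathways.

Four enriched-pathway sets are built: P1 (pathways enriched in
upregulated mRNAs), P2 (downregulated mRNAs), P3 (pooled consensus
targets of upregulated miRNAs), P4 (targets of downregulated miRNAs).
Because miRNAs repress their targets, a genuinely upregulated pathway
should surface both in P1 and in the targets of *down* miRNAs; the
intersections P1 ∩ P4 and P2 ∩ P3 therefore define the up- and
downregulated pathways, each annotated with the individual
opposite-direction miRNAs whose own target sets are enriched in it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .de import DERecord
from .enrichment import enrich
from .io_formats import GeneSet
from .targets import ConsensusTargetMap, targets_of

logger = logging.getLogger("mircross")

__all__ = [
    "PathwayQuadrant",
    "DysregulatedPathway",
    "build_quadrant",
    "intersect_inverse",
    "edges_frame",
]


@dataclass
class PathwayQuadrant:
    """The four enriched-pathway id sets P1-P4."""

    P1: set[str]  # enriched in up mRNAs
    P2: set[str]  # enriched in down mRNAs
    P3: set[str]  # enriched in targets of up miRNAs
    P4: set[str]  # enriched in targets of down miRNAs


@dataclass
class DysregulatedPathway:
    pathway_id: str
    direction: Literal["up", "down"]
    #: miRNA id -> enrichment p of that miRNA's consensus targets in this pathway
    regulating_mirnas: dict[str, float] = field(default_factory=dict)


def build_quadrant(
    de_mrnas_up: Sequence[DERecord],
    de_mrnas_down: Sequence[DERecord],
    de_mirnas_up: Sequence[DERecord],
    de_mirnas_down: Sequence[DERecord],
    consensus_map: ConsensusTargetMap,
    collection: Sequence[GeneSet],
    background,
    alpha: float = 0.05,
) -> PathwayQuadrant:
    """Run the four enrichment screens that define P1-P4."""

    def significant(query: set[str]) -> set[str]:
        if not query:
            return set()
        return {r.set_id for r in enrich(query, collection, background, alpha)
                if r.significant}

    up_genes = {r.feature_id for r in de_mrnas_up}
    down_genes = {r.feature_id for r in de_mrnas_down}
    up_targets = targets_of(consensus_map, [r.feature_id for r in de_mirnas_up])
    down_targets = targets_of(consensus_map, [r.feature_id for r in de_mirnas_down])
    for label, query in [("P1", up_genes), ("P2", down_genes),
                         ("P3", up_targets), ("P4", down_targets)]:
        if not query:
            logger.warning("%s query empty; quadrant will be empty", label)
    return PathwayQuadrant(
        P1=significant(up_genes),
        P2=significant(down_genes),
        P3=significant(up_targets),
        P4=significant(down_targets),
    )


def intersect_inverse(
    quadrant: PathwayQuadrant,
    de_mirnas_up: Sequence[DERecord] = (),
    de_mirnas_down: Sequence[DERecord] = (),
    consensus_map: ConsensusTargetMap | None = None,
    collection: Sequence[GeneSet] = (),
    background=(),
    alpha: float = 0.05,
    mirna_attribution: Literal["enrichment", "membership"] = "enrichment",
) -> list[DysregulatedPathway]:
    """Intersect the quadrants under the inverse-regulation assumption.

    Upregulated pathways = P1 ∩ P4; downregulated = P2 ∩ P3.  Each
    retained pathway's ``regulating_mirnas`` are the opposite-direction
    DE miRNAs whose own consensus-target set is enriched in that pathway
    at ``alpha`` (default), or that merely have a target in the pathway
    when ``mirna_attribution="membership"``.
    """
    up = quadrant.P1 & quadrant.P4
    down = quadrant.P2 & quadrant.P3
    both = up & down
    if both:
        raise ValueError(f"pathway(s) in both directions: {sorted(both)}")
    by_id = {gs.set_id: gs for gs in collection}

    def attribute(pathway_id: str, mirnas: Sequence[DERecord]) -> dict[str, float]:
        if consensus_map is None or pathway_id not in by_id:
            return {}
        out: dict[str, float] = {}
        for rec in mirnas:
            tset = consensus_map.targets.get(rec.feature_id, set())
            if not tset:
                continue
            if mirna_attribution == "membership":
                if tset & by_id[pathway_id].genes:
                    out[rec.feature_id] = float("nan")
                continue
            results = enrich(tset, [by_id[pathway_id]], background, alpha)
            for r in results:
                if r.set_id == pathway_id and r.significant:
                    out[rec.feature_id] = r.test.p_value
        return out

    dys: list[DysregulatedPathway] = []
    # up pathways are repressed targets of *down* miRNAs, and vice versa
    for pid in sorted(up):
        dys.append(DysregulatedPathway(pid, "up", attribute(pid, de_mirnas_down)))
    for pid in sorted(down):
        dys.append(DysregulatedPathway(pid, "down", attribute(pid, de_mirnas_up)))
    return dys


def edges_frame(dysregulated: Sequence[DysregulatedPathway]) -> pd.DataFrame:
    """miRNA-pathway regulatory edges with -log10 p weights for export."""
    rows = []
    for dp in dysregulated:
        for mirna, p in sorted(dp.regulating_mirnas.items()):
            weight = float("nan") if np.isnan(p) else -np.log10(max(p, 1e-300))
            rows.append(
                {"mirna": mirna, "pathway": dp.pathway_id,
                 "pathway_direction": dp.direction, "p": p,
                 "neg_log10_p": weight}
            )
    return pd.DataFrame(
        rows, columns=["mirna", "pathway", "pathway_direction", "p", "neg_log10_p"]
    )
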