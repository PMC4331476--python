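"""Consensus filtering of multi-tool miRNA-target predictions.

Individual prediction tools have high false-positive rates; requiring a
pair to be reported by at least 4 of the 10 tools in the roster keeps
the intersection-of-evidence pairs.  Tools are opaque labels here — only
the distinct-tool count per (miRNA, gene) pair matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger("mircross")

__all__ = ["TOOL_ROSTER", "ConsensusTargetMap", "consensus_filter", "targets_of"]

#: The ten target-prediction tools whose calls are integrated.
TOOL_ROSTER: tuple[str, ...] = (
    "miRanda",
    "TargetScan",
    "DIANA-microT",
    "mirSVR",
    "PicTar",
    "RNA22",
    "RNAhybrid",
    "PITA",
    "MirTarget2",
    "TargetMiner",
)


@dataclass
class ConsensusTargetMap:
    """miRNA -> target gene sets surviving the >= min_tools consensus."""

    targets: dict[str, set[str]]
    support: dict[tuple[str, str], int]  # (mirna, gene) -> distinct-tool count
    min_tools: int

    def __post_init__(self) -> None:
        for mirna, genes in self.targets.items():
            for g in genes:
                if self.support.get((mirna, g), 0) < self.min_tools:
                    raise ValueError(
                        f"pair ({mirna}, {g}) retained with support "
                        f"{self.support.get((mirna, g), 0)} < {self.min_tools}"
                    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"mirna": m, "gene": g, "support": self.support[(m, g)]}
            for m, genes in sorted(self.targets.items())
            for g in sorted(genes)
        ]
        return pd.DataFrame(rows, columns=["mirna", "gene", "support"])


def consensus_filter(
    table: pd.DataFrame,
    min_tools: int = 4,
    roster: tuple[str, ...] = TOOL_ROSTER,
) -> ConsensusTargetMap:
    """Keep (miRNA, gene) pairs predicted by at least ``min_tools`` distinct tools.

    ``table`` has columns (mirna, gene, tool); duplicate rows per tool
    count once.  Support counts for *all* observed pairs are kept for
    auditing, but only pairs at or above the threshold enter the map.
    """
    if min_tools < 1:
        raise ValueError("min_tools must be >= 1")
    unknown = set(table["tool"]) - set(roster)
    if unknown:
        raise ValueError(
            f"unknown tool name(s) {sorted(unknown)}; roster: {list(roster)}"
        )
    dedup = table.drop_duplicates(subset=["mirna", "gene", "tool"])
    counts = dedup.groupby(["mirna", "gene"], sort=False)["tool"].nunique()
    support = {pair: int(c) for pair, c in counts.items()}
    targets: dict[str, set[str]] = {}
    for (mirna, gene), c in support.items():
        if c >= min_tools:
            targets.setdefault(mirna, set()).add(gene)
    return ConsensusTargetMap(targets=targets, support=support, min_tools=min_tools)


def targets_of(target_map: ConsensusTargetMap, mirnas) -> set[str]:
    """Union of the consensus target sets of the given miRNAs."""
    pooled: set[str] = set()
    for m in mirnas:
        if m not in target_map.targets:
            logger.warning("miRNA %s absent from consensus map", m)
            continue
        pooled |= target_map.targets[m]
    return pooled
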