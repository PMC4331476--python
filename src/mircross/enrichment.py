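"""Hypergeometric / Fisher gene-set enrichment and BH adjustment.

The overlap test asks whether x of the n query genes falling inside an
annotation set of m genes, against a background of N genes, is more
overlap than chance.  Two tail conventions are provided:

* ``at_least`` — P(X >= x), the conventional one-sided Fisher tail used
  for enrichment calls;
* ``as_printed`` — P(X > x) = 1 - sum_{k<=x} pmf(k), the cumulative form
  some crosstalk formulations print with the sum running through k = x.

The two are linked by the tail identity at_least(x) = as_printed(x-1).
Pathway enrichment is called at P < 0.05; GO enrichment applies a
Benjamini-Hochberg step-up within each namespace (BP/CC/MF) and selects
terms at FDR < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSet

logger = logging.getLogger("mircross")

__all__ = [
    "OverlapTest",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "enrich",
    "bh_adjust",
    "go_enrich",
    "auto_background",
]

TailMode = Literal["at_least", "as_printed"]


@dataclass(frozen=True)
class OverlapTest:
    """Counts and P value of one hypergeometric overlap test."""

    N: int  # background size
    n: int  # query set size (restricted to background)
    m: int  # annotation set size
    x: int  # overlap
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.n, self.m) and self.n <= self.N and self.m <= self.N):
            raise ValueError(f"inconsistent overlap counts {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    test: OverlapTest
    overlap_genes: frozenset[str]
    significant: bool
    adjusted_p: float = float("nan")  # GO mode only

    def __post_init__(self) -> None:
        if len(self.overlap_genes) != self.test.x:
            raise ValueError("overlap gene list inconsistent with x")


def hypergeom_upper_tail(
    x: int, N: int, n: int, m: int, mode: TailMode = "at_least"
) -> float:
    """Upper-tail probability of drawing x of the m marked genes in n draws.

    ``at_least`` returns P(X >= x); ``as_printed`` returns P(X > x).
    """
    if not (0 <= x <= min(n, m) and 0 <= n <= N and 0 <= m <= N):
        raise ValueError(f"inconsistent counts x={x}, N={N}, n={n}, m={m}")
    # scipy's sf(k) = P(X > k)
    if mode == "at_least":
        return float(hypergeom.sf(x - 1, N, m, n))
    if mode == "as_printed":
        return float(hypergeom.sf(x, N, m, n))
    raise ValueError(f"unknown tail mode {mode!r}")


def auto_background(collections: Iterable[Iterable[GeneSet]]) -> frozenset[str]:
    """Union of all genes annotated anywhere in the given collections."""
    bg: set[str] = set()
    for coll in collections:
        for gs in coll:
            bg |= gs.genes
    return frozenset(bg)


def enrich(
    query_genes: Iterable[str],
    collection: Sequence[GeneSet],
    background: Iterable[str],
    alpha: float = 0.05,
    mode: TailMode = "at_least",
    min_set_size: int = 2,
) -> list[EnrichmentResult]:
    """One-sided overlap test of the query against every set in the collection.

    Query genes outside the background are dropped with a warning.  Sets
    smaller than ``min_set_size`` (after background restriction) are
    skipped.  Results are sorted by ascending p, ties broken by set_id;
    ``significant`` flags p < alpha (strict).
    """
    background = frozenset(background)
    query = set(query_genes)
    outside = query - background
    if outside:
        logger.warning(
            "%d query gene(s) outside background dropped", len(outside)
        )
        query &= background
    if not query:
        logger.warning("query empty after background restriction")
        return []
    N, n = len(background), len(query)
    results = []
    for gs in collection:
        members = gs.genes & background
        if len(members) < min_set_size:
            logger.warning("set %s smaller than %d in background; skipped",
                           gs.set_id, min_set_size)
            continue
        overlap = frozenset(query & members)
        p = hypergeom_upper_tail(len(overlap), N, n, len(members), mode)
        results.append(
            EnrichmentResult(
                set_id=gs.set_id,
                test=OverlapTest(N=N, n=n, m=len(members), x=len(overlap), p_value=p),
                overlap_genes=overlap,
                significant=p < alpha,
            )
        )
    results.sort(key=lambda r: (r.test.p_value, r.set_id))
    return results


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def go_enrich(
    query_genes: Iterable[str],
    go_collection: Sequence[GeneSet],
    background: Iterable[str],
    fdr: float = 0.05,
    mode: TailMode = "at_least",
) -> list[EnrichmentResult]:
    """GO-term enrichment with BH adjustment within each namespace.

    Namespace (BP/CC/MF) is read from the term's ``name`` field; terms
    without a recognizable namespace share an "unspecified" stratum.
    Selection is strict: adjusted_p < fdr.
    """
    def namespace(gs: GeneSet) -> str:
        tag = gs.name.split("|")[0].strip().upper()
        return tag if tag in {"BP", "CC", "MF"} else "UNSPECIFIED"

    raw = enrich(query_genes, go_collection, background, alpha=1.0, mode=mode)
    by_ns: dict[str, list[EnrichmentResult]] = {}
    for r in raw:
        gs = next(g for g in go_collection if g.set_id == r.set_id)
        by_ns.setdefault(namespace(gs), []).append(r)
    adjusted: list[EnrichmentResult] = []
    for ns_results in by_ns.values():
        adj = bh_adjust([r.test.p_value for r in ns_results])
        for r, q in zip(ns_results, adj):
            adjusted.append(
                EnrichmentResult(
                    set_id=r.set_id,
                    test=r.test,
                    overlap_genes=r.overlap_genes,
                    significant=bool(q < fdr),
                    adjusted_p=float(q),
                )
            )
    adjusted.sort(key=lambda r: (r.adjusted_p, r.test.p_value, r.set_id))
    return adjusted
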