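"""Synthetic two-group miRNA/mRNA study with planted ground truth.

The generator emulates every statistical structure the analysis
assumes, at desk scale:

* two-group log2 expression with planted ±effect_log2 shifts in cases
  and Gaussian noise, plus an optional monotone per-array intensity bias
  for the lowess normalization to remove;
* raw-intensity miRNA arrays with an additive array background and a few
  empty (background-level) probes, for the background-subtraction +
  quantile-normalization path;
* ten prediction tools reporting each true miRNA-target pair with a set
  sensitivity and each false pair with a small false-positive rate;
* pathway collections in which two crosstalk blocks (an up block and a
  down block) share exactly ``n_shared`` mediator genes per pair, each
  planted pathway carries key genes targeted by inversely regulated
  miRNAs, and every planted pathway graph holds one dense signature
  neighborhood plus one signature gene placed at graph distance >= k;
* miRNA loci with planted same-chromosome clusters (gaps <= 10 kb)
  whose members regulate the same pathway.

All randomness flows from one seed through named per-simulation
generators, so adding a simulation never perturbs another's stream.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import (
    GeneSet,
    GenomicInterval,
    PathwayGraph,
    write_bed,
    write_expression_tsv,
    write_gmt,
    write_groups,
    write_pathway_graph,
    write_predictions,
)
from .de import ExpressionMatrix
from .targets import TOOL_ROSTER

__all__ = [
    "SimParams",
    "PlantedTruth",
    "SyntheticBundle",
    "simulate_expression",
    "simulate_tool_predictions",
    "simulate_pathways",
    "simulate_go_terms",
    "simulate_mirna_loci",
    "simulate_bundle",
    "write_bundle",
]


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named child generator: independent stream per sub-simulation."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass
class SimParams:
    """Study conditions of the synthetic design.

    Sample sizes default to the 20-case / 10-control design of the mRNA
    arrays; feature counts are scaled down (2,000 genes, 200 miRNAs)
    while the screening structure (100 planted DE genes per direction,
    21 up / 25 down DE miRNAs, 10 tools, 2 up + 4 down planted
    pathways, k = 4, 10 kb clusters) mirrors the study's.
    """

    n_genes: int = 2000
    n_mirnas: int = 200
    n_case: int = 20
    n_control: int = 10
    effect_log2: float = 1.5
    noise_sd: float = 0.5
    # differential expression
    n_de_genes: int = 100          # per direction
    n_de_mirnas_up: int = 21
    n_de_mirnas_down: int = 25
    # pathway structure
    n_pathways: int = 20           # total incl. background pathways
    pathway_size: int = 30
    n_shared: int = 5              # block-mediator genes per crosstalk block
    n_up_pathways: int = 2
    n_down_pathways: int = 4
    n_singletons: int = 2          # single-pathway key genes per planted pathway
    n_extra_de: int = 6            # DE-but-untargeted genes per planted pathway
    # regulators (miRNAs wired to pathways)
    n_regulators_up: int = 12
    n_regulators_down: int = 2
    extra_targets_per_regulator: int = 5
    targets_per_nonregulator: int = 8
    # prediction tools
    tool_count: int = 10
    tool_sensitivity: float = 0.8
    tool_fpr: float = 0.005
    # array artefacts
    array_bias_amp: float = 0.2
    mirna_background: tuple[float, float] = (20.0, 40.0)
    # graph / genomics structure
    lap_k: int = 4
    cluster_gap_bp: int = 10_000
    n_mirna_clusters: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_mirnas < 1:
            raise ValueError("feature counts must be positive")
        if self.n_case < 3 or self.n_control < 3:
            raise ValueError("need >= 3 samples per group")
        if self.n_shared >= self.pathway_size:
            raise ValueError("n_shared must be < pathway_size")
        if not (0 <= self.tool_fpr < self.tool_sensitivity <= 1):
            raise ValueError("need tool_sensitivity > tool_fpr in [0, 1]")
        if self.lap_k < 2:
            raise ValueError("lap_k must be >= 2")
        planted = self.n_up_pathways + self.n_down_pathways
        if planted > self.n_pathways:
            raise ValueError("planted pathways exceed n_pathways")
        if self.effect_log2 > 0:
            if 2 * self.n_de_genes > self.n_genes:
                raise ValueError("planted DE genes exceed n_genes")
            if (self.n_de_mirnas_up + self.n_de_mirnas_down
                    > self.n_mirnas - self.n_empty_probes):
                raise ValueError("planted DE miRNAs exceed usable miRNA probes")

    @property
    def n_empty_probes(self) -> int:
        """Background-level probes reserved for background estimation."""
        return max(4, int(np.ceil(0.03 * self.n_mirnas)))


@dataclass
class PlantedTruth:
    """Ground truth written alongside every bundle."""

    de_mrnas_up: dict[str, float] = field(default_factory=dict)   # gene -> log2 effect
    de_mrnas_down: dict[str, float] = field(default_factory=dict)
    de_mirnas_up: dict[str, float] = field(default_factory=dict)
    de_mirnas_down: dict[str, float] = field(default_factory=dict)
    true_targets: dict[str, list[str]] = field(default_factory=dict)  # mirna -> genes
    enriched_pathways_up: list[str] = field(default_factory=list)
    enriched_pathways_down: list[str] = field(default_factory=list)
    mediator_genes: list[str] = field(default_factory=list)
    key_genes: dict[str, list[str]] = field(default_factory=dict)  # pathway -> genes
    pathway_regulators: dict[str, list[str]] = field(default_factory=dict)
    planted_laps: dict[str, list[str]] = field(default_factory=dict)  # pathway -> dense set
    mirna_clusters: list[list[str]] = field(default_factory=list)
    crosstalk_pairs: list[list[str]] = field(default_factory=list)

    def validate(self) -> None:
        if set(self.de_mrnas_up) & set(self.de_mrnas_down):
            raise ValueError("planted up/down mRNA sets overlap")
        if set(self.de_mirnas_up) & set(self.de_mirnas_down):
            raise ValueError("planted up/down miRNA sets overlap")
        for mirna, genes in self.true_targets.items():
            for g in genes:
                if mirna in self.de_mirnas_up and g not in self.de_mrnas_down:
                    raise ValueError(f"target pair ({mirna},{g}) not inverse")
                if mirna in self.de_mirnas_down and g not in self.de_mrnas_up:
                    raise ValueError(f"target pair ({mirna},{g}) not inverse")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticBundle:
    params: SimParams
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    predictions: pd.DataFrame
    pathways: list[GeneSet]
    graphs: dict[str, PathwayGraph]
    go_terms: list[GeneSet]
    mirna_loci: list[GenomicInterval]
    truth: PlantedTruth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _mirna_ids(n: int) -> list[str]:
    return [f"hsa-miR-s{i}" for i in range(1, n + 1)]


def simulate_expression(
    params: SimParams,
) -> tuple[ExpressionMatrix, ExpressionMatrix, PlantedTruth]:
    """Two-group mRNA (log2) and miRNA (raw intensity) matrices.

    Background features share the same distribution in both groups;
    planted features are shifted by ±effect_log2 in cases.  With
    ``effect_log2 = 0`` the planted DE sets are empty by construction.
    Deterministic given ``params.seed``.
    """
    rng = _rng(params.seed, "expression")
    genes = _gene_ids(params.n_genes)
    mirnas = _mirna_ids(params.n_mirnas)
    samples = [f"MG{i:02d}" for i in range(1, params.n_case + 1)] + [
        f"CT{i:02d}" for i in range(1, params.n_control + 1)
    ]
    group = {s: ("case" if s.startswith("MG") else "control") for s in samples}
    n_samp = len(samples)
    truth = PlantedTruth()

    # ---- planted DE assignment -------------------------------------------
    if params.effect_log2 > 0:
        de_genes = rng.choice(params.n_genes, 2 * params.n_de_genes, replace=False)
        for i in de_genes[: params.n_de_genes]:
            truth.de_mrnas_up[genes[i]] = params.effect_log2
        for i in de_genes[params.n_de_genes:]:
            truth.de_mrnas_down[genes[i]] = -params.effect_log2
        n_de_mir = params.n_de_mirnas_up + params.n_de_mirnas_down
        # reserve the trailing empty probes (see below) from DE assignment
        de_mirs = rng.choice(
            params.n_mirnas - params.n_empty_probes, n_de_mir, replace=False
        )
        for i in de_mirs[: params.n_de_mirnas_up]:
            truth.de_mirnas_up[mirnas[i]] = params.effect_log2
        for i in de_mirs[params.n_de_mirnas_up:]:
            truth.de_mirnas_down[mirnas[i]] = -params.effect_log2

    # ---- mRNA: log2 scale with monotone per-array bias -------------------
    baseline = rng.uniform(6.0, 12.0, size=params.n_genes)
    X = baseline[:, None] + rng.normal(0.0, params.noise_sd, (params.n_genes, n_samp))
    case_cols = np.array([group[s] == "case" for s in samples])
    effect = np.zeros(params.n_genes)
    for g, e in {**truth.de_mrnas_up, **truth.de_mrnas_down}.items():
        effect[genes.index(g)] = e
    X[:, case_cols] += effect[:, None]
    if params.array_bias_amp > 0:
        amp = rng.uniform(-params.array_bias_amp, params.array_bias_amp, n_samp)
        X = X + amp[None, :] * np.tanh((X - 9.0) / 3.0)
    mrna = ExpressionMatrix(
        values=pd.DataFrame(X, index=genes, columns=samples), group=dict(group)
    )

    # ---- miRNA: raw intensities with additive background -----------------
    n_empty = params.n_empty_probes
    mir_base = rng.uniform(8.0, 13.0, size=params.n_mirnas)
    L = mir_base[:, None] + rng.normal(0.0, params.noise_sd, (params.n_mirnas, n_samp))
    mir_effect = np.zeros(params.n_mirnas)
    for m, e in {**truth.de_mirnas_up, **truth.de_mirnas_down}.items():
        mir_effect[mirnas.index(m)] = e
    L[:, case_cols] += mir_effect[:, None]
    scale = rng.uniform(0.8, 1.25, n_samp)
    bg = rng.uniform(*params.mirna_background, size=n_samp)
    raw = (2.0 ** L) * scale[None, :] + bg[None, :]
    # empty probes: background-level signal only
    raw[-n_empty:, :] = bg[None, :] + np.abs(rng.normal(0.0, 2.0, (n_empty, n_samp)))
    mirna = ExpressionMatrix(
        values=pd.DataFrame(raw, index=mirnas, columns=samples), group=dict(group)
    )
    truth.validate()
    return mrna, mirna, truth


# ---------------------------------------------------------------------------
# Pathways, regulators, targets
# ---------------------------------------------------------------------------

def simulate_pathways(
    truth: PlantedTruth, params: SimParams
) -> tuple[list[GeneSet], dict[str, PathwayGraph]]:
    """Plant the pathway collection, crosstalk blocks, key genes and graphs.

    Fills in ``truth``: enriched pathways per direction, mediator genes,
    per-pathway key genes, miRNA regulators, true targets and planted
    LAP signature neighborhoods.  Within each crosstalk block every
    pathway pair shares exactly ``n_shared`` mediator genes; pathways
    from different blocks share nothing.
    """
    rng = _rng(params.seed, "pathways")
    genes = _gene_ids(params.n_genes)
    up_pool = sorted(truth.de_mrnas_up)
    down_pool = sorted(truth.de_mrnas_down)
    non_de = [g for g in genes if g not in truth.de_mrnas_up and g not in truth.de_mrnas_down]
    rng.shuffle(non_de)
    non_de_iter = iter(non_de)

    def take_non_de(k: int) -> list[str]:
        return [next(non_de_iter) for _ in range(k)]

    def take(pool: list[str], k: int) -> list[str]:
        k = min(k, len(pool))
        picked = [pool.pop() for _ in range(k)]
        return picked

    # shuffle DE pools once so draws are random but non-overlapping
    rng.shuffle(up_pool)
    rng.shuffle(down_pool)

    up_ids = [f"PWU{i}" for i in range(1, params.n_up_pathways + 1)]
    down_ids = [f"PWD{i}" for i in range(1, params.n_down_pathways + 1)]
    n_bg = params.n_pathways - len(up_ids) - len(down_ids)
    bg_ids = [f"PWB{i:02d}" for i in range(1, n_bg + 1)]

    truth.enriched_pathways_up = list(up_ids)
    truth.enriched_pathways_down = list(down_ids)

    def build_block(ids: list[str], pool: list[str], direction: str) -> dict[str, list[str]]:
        """Assign gene memberships for one crosstalk block; returns per-pathway key genes."""
        mediators = take(pool, params.n_shared) if len(ids) >= 2 else []
        truth.mediator_genes.extend(mediators)
        members: dict[str, list[str]] = {}
        key: dict[str, list[str]] = {}
        for pid in ids:
            singles = take(pool, params.n_singletons)
            extras = take(pool, params.n_extra_de)
            filler = take_non_de(
                params.pathway_size - len(mediators) - len(singles) - len(extras)
            )
            members[pid] = mediators + singles + extras + filler
            key[pid] = mediators + singles
            truth.key_genes[pid] = key[pid]
        if mediators:
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    truth.crosstalk_pairs.append([a, b])
        return members

    up_members = build_block(up_ids, up_pool, "up")
    down_members = build_block(down_ids, down_pool, "down")

    collection: list[GeneSet] = []
    graphs: dict[str, PathwayGraph] = {}
    all_members = {**up_members, **down_members}
    for pid in bg_ids:
        all_members[pid] = take_non_de(params.pathway_size)

    # ---- regulators and true targets -------------------------------------
    rng2 = _rng(params.seed, "regulators")
    up_mirs = sorted(truth.de_mirnas_up)
    down_mirs = sorted(truth.de_mirnas_down)
    reg_up = list(rng2.permutation(up_mirs))[: params.n_regulators_up]
    reg_down = list(rng2.permutation(down_mirs))[: params.n_regulators_down]
    # up miRNAs repress down pathways' key genes; down miRNAs repress up ones
    for i, m in enumerate(reg_up):
        pid = down_ids[i % len(down_ids)] if down_ids else None
        if pid is None:
            break
        truth.pathway_regulators.setdefault(pid, []).append(m)
        extra = [g for g in down_pool[: params.extra_targets_per_regulator]]
        truth.true_targets[m] = sorted(set(truth.key_genes[pid]) | set(extra))
    for i, m in enumerate(reg_down):
        pid = up_ids[i % len(up_ids)] if up_ids else None
        if pid is None:
            break
        truth.pathway_regulators.setdefault(pid, []).append(m)
        extra = [g for g in up_pool[: params.extra_targets_per_regulator]]
        truth.true_targets[m] = sorted(set(truth.key_genes[pid]) | set(extra))
    # remaining DE miRNAs target inverse DE genes outside the planted pathways
    planted_genes = {g for mem in all_members.values() for g in mem}
    free_down = [g for g in down_pool if g not in planted_genes]
    free_up = [g for g in up_pool if g not in planted_genes]
    for m in up_mirs:
        if m in truth.true_targets or not free_down:
            continue
        k = min(params.targets_per_nonregulator, len(free_down))
        truth.true_targets[m] = sorted(rng2.choice(free_down, k, replace=False))
    for m in down_mirs:
        if m in truth.true_targets or not free_up:
            continue
        k = min(params.targets_per_nonregulator, len(free_up))
        truth.true_targets[m] = sorted(rng2.choice(free_up, k, replace=False))

    # ---- gene sets and graphs --------------------------------------------
    grng = _rng(params.seed, "graphs")
    for pid, mem in all_members.items():
        collection.append(
            GeneSet(set_id=pid, name=f"synthetic pathway {pid}", genes=frozenset(mem))
        )
        key = truth.key_genes.get(pid, [])
        if len(key) >= 3:
            dense = key[:-1]  # all but one signature gene form the dense core
            far = key[-1]
            graphs[pid] = _planted_graph(pid, mem, dense, far, params.lap_k, grng)
            truth.planted_laps[pid] = sorted(dense)
        else:
            graphs[pid] = _background_graph(pid, mem, grng)
    truth.validate()
    return collection, graphs


def _planted_graph(
    pid: str,
    members: Sequence[str],
    dense: Sequence[str],
    far: str,
    k: int,
    rng: np.random.Generator,
) -> PathwayGraph:
    """Graph with a signature clique and one signature gene at distance >= k."""
    g = nx.Graph()
    g.add_nodes_from(members)
    dense = list(dense)
    for i, a in enumerate(dense):
        for b in dense[i + 1:]:
            g.add_edge(a, b)
    others = [m for m in members if m not in dense and m != far]
    # chain of k-1 linkers: far is exactly k edges from the nearest clique gene
    linkers = others[: k - 1]
    chain = [far, *linkers, dense[0]]
    for a, b in zip(chain, chain[1:]):
        g.add_edge(a, b)
    # attach the rest to the near side only, so no shortcut to `far` appears
    near = list(dense)
    for node in others[k - 1:]:
        g.add_edge(node, near[int(rng.integers(len(near)))])
        near.append(node)
    return PathwayGraph(pathway_id=pid, graph=g)


def _background_graph(
    pid: str, members: Sequence[str], rng: np.random.Generator
) -> PathwayGraph:
    """Random connected graph: a random tree plus a few chords."""
    g = nx.Graph()
    nodes = list(members)
    g.add_nodes_from(nodes)
    for i in range(1, len(nodes)):
        g.add_edge(nodes[i], nodes[int(rng.integers(i))])
    for _ in range(max(1, len(nodes) // 5)):
        a, b = rng.choice(len(nodes), 2, replace=False)
        if a != b:
            g.add_edge(nodes[int(a)], nodes[int(b)])
    return PathwayGraph(pathway_id=pid, graph=g)


# ---------------------------------------------------------------------------
# Tool predictions
# ---------------------------------------------------------------------------

def simulate_tool_predictions(truth: PlantedTruth, params: SimParams) -> pd.DataFrame:
    """Per-tool (mirna, gene, tool) prediction rows.

    Each of ``tool_count`` tools reports every true pair independently
    with probability ``tool_sensitivity`` and every false pair with
    probability ``tool_fpr``.
    """
    rng = _rng(params.seed, "predictions")
    genes = np.array(_gene_ids(params.n_genes))
    mirnas = np.array(_mirna_ids(params.n_mirnas))
    tools = list(TOOL_ROSTER[: params.tool_count])
    true_pairs = [
        (m, g) for m in sorted(truth.true_targets) for g in truth.true_targets[m]
    ]
    true_set = set(true_pairs)
    rows: list[tuple[str, str, str]] = []
    for tool in tools:
        if true_pairs:
            keep = rng.random(len(true_pairs)) < params.tool_sensitivity
            rows.extend((m, g, tool) for (m, g), k in zip(true_pairs, keep) if k)
        if params.tool_fpr > 0:
            n_universe = params.n_mirnas * params.n_genes
            n_fp = rng.binomial(n_universe, params.tool_fpr)
            idx = rng.choice(n_universe, size=n_fp, replace=False)
            mi, gi = np.divmod(idx, params.n_genes)
            for m, g in zip(mirnas[mi], genes[gi]):
                if (m, g) not in true_set:
                    rows.append((m, g, tool))
    return pd.DataFrame(rows, columns=["mirna", "gene", "tool"])


# ---------------------------------------------------------------------------
# GO terms
# ---------------------------------------------------------------------------

def simulate_go_terms(truth: PlantedTruth, params: SimParams) -> list[GeneSet]:
    """Small GO collection: per namespace, terms loaded with key genes
    plus background terms of random non-DE genes."""
    rng = _rng(params.seed, "go")
    genes = _gene_ids(params.n_genes)
    key = sorted({g for gs in truth.key_genes.values() for g in gs})
    non_de = [
        g for g in genes if g not in truth.de_mrnas_up and g not in truth.de_mrnas_down
    ]
    terms: list[GeneSet] = []
    for ns in ("BP", "MF", "CC"):
        for i in range(1, 3):
            loaded = (
                list(rng.choice(key, min(8, len(key)), replace=False)) if key else []
            )
            filler = list(rng.choice(non_de, 10, replace=False))
            terms.append(
                GeneSet(
                    set_id=f"GO:{ns}{i:04d}",
                    name=f"{ns}|planted term {i}",
                    genes=frozenset(loaded + filler),
                )
            )
        for i in range(3, 6):
            terms.append(
                GeneSet(
                    set_id=f"GO:{ns}{i:04d}",
                    name=f"{ns}|background term {i}",
                    genes=frozenset(rng.choice(non_de, 15, replace=False)),
                )
            )
    return terms


# ---------------------------------------------------------------------------
# miRNA loci
# ---------------------------------------------------------------------------

def simulate_mirna_loci(
    truth: PlantedTruth, params: SimParams
) -> list[GenomicInterval]:
    """Place miRNA genes on chromosomes with planted <=10 kb clusters.

    Planted clusters group same-direction regulators of the same pathway
    with consecutive gaps well under ``cluster_gap_bp``; all other
    miRNAs sit at least 5x the gap apart or on other chromosomes.
    """
    rng = _rng(params.seed, "loci")
    mirnas = _mirna_ids(params.n_mirnas)
    gap = params.cluster_gap_bp
    clustered: list[list[str]] = []
    used: set[str] = set()
    # pick pathways with >= 2 regulators; co-locate two of their regulators
    for pid, regs in sorted(truth.pathway_regulators.items()):
        if len(clustered) >= params.n_mirna_clusters:
            break
        pair = [m for m in regs if m not in used][:2]
        if len(pair) == 2:
            clustered.append(pair)
            used.update(pair)
    truth.mirna_clusters = [sorted(c) for c in clustered]

    loci: list[GenomicInterval] = []
    chroms = [f"chr{c}" for c in list(range(1, 23)) + ["X"]]
    for ci, members in enumerate(clustered):
        chrom = chroms[ci % len(chroms)]
        pos = 1_000_000 + ci * 10_000_000
        for m in members:
            loci.append(GenomicInterval(m, chrom, pos, pos + 80, "+"))
            pos += 80 + int(rng.integers(1_000, gap // 2))  # gap well within limit
    spread = iter(range(len(mirnas)))
    for m in mirnas:
        if m in used:
            continue
        i = next(spread)
        chrom = chroms[(i + len(clustered)) % len(chroms)]
        start = 40_000_000 + (i // len(chroms)) * (6 * gap)
        loci.append(GenomicInterval(m, chrom, start, start + 80, "+"))
    return loci


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

def simulate_bundle(params: SimParams | None = None) -> SyntheticBundle:
    """Run every sub-simulation in order and return the full fixture bundle."""
    params = params or SimParams()
    mrna, mirna, truth = simulate_expression(params)
    pathways, graphs = simulate_pathways(truth, params)
    predictions = simulate_tool_predictions(truth, params)
    go_terms = simulate_go_terms(truth, params)
    loci = simulate_mirna_loci(truth, params)
    return SyntheticBundle(
        params=params,
        mrna=mrna,
        mirna=mirna,
        predictions=predictions,
        pathways=pathways,
        graphs=graphs,
        go_terms=go_terms,
        mirna_loci=loci,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Write the bundle in the pipeline's input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(bundle.mrna, out / "mrna.tsv")
    write_expression_tsv(bundle.mirna, out / "mirna.tsv")
    write_groups(bundle.mrna.group, out / "groups.tsv")
    write_predictions(bundle.predictions, out / "predictions.tsv")
    write_gmt(bundle.pathways, out / "pathways.gmt")
    write_gmt(bundle.go_terms, out / "go.gmt")
    gdir = out / "pathway_graphs"
    gdir.mkdir(exist_ok=True)
    for pid, pg in bundle.graphs.items():
        write_pathway_graph(pg, gdir / f"{pid}.tsv")
    write_bed(bundle.mirna_loci, out / "mirna_loci.bed")
    (out / "truth.json").write_text(bundle.truth.to_json())
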