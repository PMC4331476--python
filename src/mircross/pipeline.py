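"""End-to-end driver chaining every analysis stage and writing result tables.

Stages: DE screening of mRNAs (lowess + SAM + permutation FDR, q < 0.05
and FC > 2) and miRNAs (background subtraction + quantile normalization,
FC > 2); consensus target filtering (>= 4 of 10 tools); the P1-P4
enrichment quadrant and its inverse-regulation intersection; pairwise
pathway crosstalk with hierarchical clustering; key-gene / mediator
detection and the mediation fraction; k-clique LAP mining; genomic
miRNA clustering.  ``run_all`` consumes a directory in the bundle
layout and writes every declared output table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import crosstalk as ct
from . import de as de_mod
from . import genomics, integration, lap
from .enrichment import auto_background, go_enrich
from .io_formats import (
    GeneSet,
    PathwayGraph,
    RunConfig,
    read_bed,
    read_expression_tsv,
    read_gmt,
    read_pathway_graph,
    read_predictions,
)
from .targets import consensus_filter

logger = logging.getLogger("mircross")

__all__ = ["PipelineResult", "run_all", "load_inputs"]


@dataclass
class PipelineResult:
    de_mrnas_up: list
    de_mrnas_down: list
    de_mirnas_up: list
    de_mirnas_down: list
    consensus_map: object
    quadrant: integration.PathwayQuadrant
    dysregulated: list
    crosstalk_pairs: list
    crosstalk_matrix: ct.CrosstalkMatrix | None
    key_genes: list
    mediation: float | None
    go_results: list
    laps: dict[str, list]
    mirna_clusters: list


def load_inputs(in_dir: str | Path):
    """Read a bundle-layout directory into in-memory inputs."""
    d = Path(in_dir)
    mrna = read_expression_tsv(d / "mrna.tsv", d / "groups.tsv")
    mirna = read_expression_tsv(d / "mirna.tsv", d / "groups.tsv")
    predictions = read_predictions(d / "predictions.tsv")
    pathways = read_gmt(d / "pathways.gmt")
    go_terms = read_gmt(d / "go.gmt") if (d / "go.gmt").exists() else []
    graphs: dict[str, PathwayGraph] = {}
    gdir = d / "pathway_graphs"
    if gdir.is_dir():
        for f in sorted(gdir.glob("*.tsv")):
            graphs[f.stem] = read_pathway_graph(f)
    loci = read_bed(d / "mirna_loci.bed") if (d / "mirna_loci.bed").exists() else []
    return mrna, mirna, predictions, pathways, go_terms, graphs, loci


def run_all(
    in_dir: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> PipelineResult:
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mrna, mirna, predictions, pathways, go_terms, graphs, loci = load_inputs(in_dir)

    # ---- differential expression -----------------------------------------
    sam = de_mod.SAMConfig(seed=config.seed)
    m_up, m_down, m_all = de_mod.run_de_mrna(
        mrna, config.fc_cutoff, config.de_fdr, sam
    )
    mi_up, mi_down, mi_all = de_mod.run_de_mirna(mirna, config.fc_cutoff)
    _write_de(out / "de_mrna.tsv", m_up + m_down)
    _write_de(out / "de_mirna.tsv", mi_up + mi_down)

    # ---- consensus targets -----------------------------------------------
    cmap = consensus_filter(predictions, config.consensus_min_tools)
    cmap.to_frame().to_csv(out / "consensus_targets.tsv", sep="\t", index=False)

    # ---- integration -----------------------------------------------------
    if config.background_size == "auto":
        background = auto_background([pathways])
    else:
        # explicit genome size: pad the annotated universe with ids up to N
        annotated = sorted(auto_background([pathways]))
        extra = int(config.background_size) - len(annotated)
        background = frozenset(annotated + [f"BGPAD{i}" for i in range(max(extra, 0))])
    quadrant = integration.build_quadrant(
        m_up, m_down, mi_up, mi_down, cmap, pathways, background, config.enrich_p
    )
    dys = integration.intersect_inverse(
        quadrant, mi_up, mi_down, cmap, pathways, background, config.enrich_p
    )
    edges = integration.edges_frame(dys)
    edges.to_csv(out / "mirna_pathway_edges.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"pathway": d.pathway_id, "direction": d.direction,
          "n_regulating_mirnas": len(d.regulating_mirnas)} for d in dys]
    ).to_csv(out / "dysregulated_pathways.tsv", sep="\t", index=False)

    # ---- crosstalk -------------------------------------------------------
    by_id = {gs.set_id: gs for gs in pathways}
    dys_sets = [by_id[d.pathway_id] for d in dys]
    pairs: list = []
    matrix = None
    mediation = None
    key_genes = ct.detect_key_genes(dys, pathways, cmap, m_up, m_down, mi_up, mi_down)
    if len(dys_sets) >= 2:
        pairs = ct.crosstalk_all_pairs(dys_sets, background, config.crosstalk_p)
        matrix = ct.cluster_crosstalk(pairs)
        _write_pairs(out / "crosstalk_pairs.tsv", pairs)
        matrix.neg_log10_p.to_csv(out / "crosstalk_matrix.tsv", sep="\t")
        (out / "dendrogram.nwk").write_text(
            ct.linkage_to_newick(matrix.linkage_matrix, matrix.pathway_ids)
        )
        sig = [p for p in pairs if p.significant]
        if sig:
            mediators = [k.gene for k in key_genes if k.is_mediator]
            if mediators:
                mediation = ct.mediation_fraction(sig, mediators)
    pd.DataFrame(
        [{"gene": k.gene, "direction": k.direction,
          "pathways": ",".join(sorted(k.pathways)),
          "mirnas": ",".join(sorted(k.regulating_mirnas)),
          "is_mediator": k.is_mediator} for k in key_genes]
    ).to_csv(out / "key_genes.tsv", sep="\t", index=False)
    with open(out / "mediation_summary.tsv", "w") as fh:
        fh.write("statistic\tvalue\n")
        fh.write(f"n_significant_pairs\t{sum(p.significant for p in pairs)}\n")
        fh.write(f"mediation_fraction\t{'' if mediation is None else mediation}\n")

    # ---- GO enrichment of key genes --------------------------------------
    go_results = []
    if go_terms and key_genes:
        go_bg = background | auto_background([go_terms])
        go_results = go_enrich(
            [k.gene for k in key_genes], go_terms, go_bg, config.go_fdr
        )
        pd.DataFrame(
            [{"term": r.set_id, "p": r.test.p_value, "fdr": r.adjusted_p,
              "x": r.test.x, "m": r.test.m, "significant": r.significant}
             for r in go_results]
        ).to_csv(out / "go_enrichment.tsv", sep="\t", index=False)

    # ---- LAP mining ------------------------------------------------------
    lap_cfg = lap.LAPConfig(k=config.lap_k)
    laps: dict[str, list] = {}
    all_key = {k.gene for k in key_genes}
    lap_rows = []
    for d in dys:
        pg = graphs.get(d.pathway_id)
        if pg is None:
            continue
        sig_genes = lap.signature_genes(pg, m_up, m_down, cmap, mi_up, mi_down)
        mined = lap.mine_laps(pg, sig_genes, lap_cfg)
        mined = lap.lap_enrichment(mined, all_key, background)
        laps[d.pathway_id] = mined
        for l in mined:
            lap_rows.append(
                {"lap_id": l.lap_id, "pathway": l.pathway_id,
                 "signature": ",".join(sorted(l.signature_genes)),
                 "linkers": ",".join(sorted(l.linker_genes)),
                 "p": l.enrichment_p}
            )
    pd.DataFrame(
        lap_rows, columns=["lap_id", "pathway", "signature", "linkers", "p"]
    ).to_csv(out / "laps.tsv", sep="\t", index=False)

    # ---- miRNA genomic clusters ------------------------------------------
    clusters = []
    if loci:
        de_mir_ids = {r.feature_id for r in mi_up + mi_down}
        de_loci = [iv for iv in loci if iv.feature_id in de_mir_ids]
        clusters = genomics.cluster_mirnas(de_loci, config.cluster_gap_bp)
        clusters = genomics.cluster_pathway_coregulation(clusters, edges)
        pd.DataFrame(
            [{"cluster_id": c.cluster_id, "chrom": c.chrom,
              "members": ",".join(c.member_ids), "span_bp": c.span,
              "coregulated_pathways": ",".join(sorted(c.coregulated_pathways))}
             for c in clusters]
        ).to_csv(out / "mirna_clusters.tsv", sep="\t", index=False)

    return PipelineResult(
        de_mrnas_up=m_up, de_mrnas_down=m_down,
        de_mirnas_up=mi_up, de_mirnas_down=mi_down,
        consensus_map=cmap, quadrant=quadrant, dysregulated=dys,
        crosstalk_pairs=pairs, crosstalk_matrix=matrix,
        key_genes=key_genes, mediation=mediation, go_results=go_results,
        laps=laps, mirna_clusters=clusters,
    )


def _write_de(path: Path, records) -> None:
    pd.DataFrame(
        [{"feature": r.feature_id, "direction": r.direction,
          "fold_change": r.fold_change, "d_stat": r.d_stat,
          "q_value": r.q_value} for r in records]
    ).to_csv(path, sep="\t", index=False)


def _write_pairs(path: Path, pairs) -> None:
    pd.DataFrame(
        [{"pathway_a": p.pathway_a, "pathway_b": p.pathway_b,
          "N": p.N, "n": p.n, "m": p.m, "x": p.x, "p": p.p_value,
          "shared_genes": ",".join(sorted(p.shared_genes)),
          "significant": p.significant} for p in pairs]
    ).to_csv(path, sep="\t", index=False)
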