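"""Pathway crosstalk pairs, clustering, key genes and mediation."""

import itertools

import numpy as np
import pytest

import dendropy

from mircross.crosstalk import (
    CrosstalkPair,
    cluster_crosstalk,
    crosstalk_all_pairs,
    detect_key_genes,
    linkage_to_newick,
    mediation_fraction,
)
from mircross.de import DERecord
from mircross.integration import DysregulatedPathway
from mircross.io_formats import GeneSet
from mircross.targets import TOOL_ROSTER, consensus_filter


def rec(fid, direction="up"):
    lfc = 2.0 if direction == "up" else -2.0
    return DERecord(fid, lfc, 0.0, lfc, 4.0, direction, 1.0, 0.01)


def cmap_from(pairs):
    import pandas as pd

    rows = [(m, g, t) for m, g in pairs for t in TOOL_ROSTER[:4]]
    return consensus_filter(pd.DataFrame(rows, columns=["mirna", "gene", "tool"]), 4)


def pair(a, b, p, shared=(), N=100):
    shared = frozenset(shared)
    return CrosstalkPair(a, b, N, 10, 10, len(shared), p, shared, p < 0.05)


BG = [f"B{i}" for i in range(20)]


class TestCrosstalkPairs:
    def test_invariant_to_pathway_order(self):
        sets = [
            GeneSet("A", "", frozenset(BG[:6])),
            GeneSet("B", "", frozenset(BG[4:10])),
            GeneSet("C", "", frozenset(BG[8:14])),
        ]
        p1 = crosstalk_all_pairs(sets, BG)
        p2 = crosstalk_all_pairs(sets[::-1], BG)
        key = lambda ps: {(p.pathway_a, p.pathway_b): p.p_value for p in ps}
        assert key(p1) == key(p2)

    def test_identical_sets_as_printed_p_zero(self):
        sets = [GeneSet("A", "", frozenset(BG[:5])), GeneSet("B", "", frozenset(BG[:5]))]
        (p,) = crosstalk_all_pairs(sets, BG, mode="as_printed")
        assert p.p_value == pytest.approx(0.0, abs=1e-15)

    def test_disjoint_sets_at_least_p_one(self):
        sets = [GeneSet("A", "", frozenset(BG[:5])), GeneSet("B", "", frozenset(BG[5:10]))]
        (p,) = crosstalk_all_pairs(sets, BG)
        assert p.p_value == pytest.approx(1.0) and not p.significant

    def test_known_exact_value(self):
        bg10 = BG[:10]
        sets = [
            GeneSet("A", "", frozenset(bg10[:5])),
            GeneSet("B", "", frozenset(bg10[2:6])),  # overlap {B2,B3,B4} = 3
        ]
        (p,) = crosstalk_all_pairs(sets, bg10)
        assert (p.n, p.m, p.x) == (5, 4, 3)
        assert p.p_value == pytest.approx(66 / 252, rel=1e-12)

    def test_adding_shared_gene_never_increases_p(self):
        # monotonicity on a grid, N fixed
        for n, m in itertools.product(range(2, 8), repeat=2):
            prev = 1.1
            for x in range(0, min(n, m) + 1):
                from mircross.enrichment import hypergeom_upper_tail

                p = hypergeom_upper_tail(x, 20, n, m)
                assert p <= prev + 1e-12
                prev = p

    def test_missing_pathway_needs_two(self):
        with pytest.raises(ValueError):
            crosstalk_all_pairs([GeneSet("A", "", frozenset(BG[:5]))], BG)


class TestClusterCrosstalk:
    def test_identical_rows_merge_first(self):
        # A and B have identical crosstalk profiles (same row of the matrix)
        pairs = [
            pair("A", "B", 1.0),
            pair("A", "C", 1e-4, ["B0"]),
            pair("B", "C", 1e-4, ["B1"]),
        ]
        m = cluster_crosstalk(pairs, n_clusters=2)
        assert set(m.linkage_matrix[0, :2].astype(int)) == {0, 1}  # A, B
        assert m.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert m.cluster_labels["A"] == m.cluster_labels["B"] != m.cluster_labels["C"]

    def test_merge_order_matches_brute_force_oracle(self):
        # hand-built 3x3 -log10 p matrix via chosen p-values
        pairs = [
            pair("A", "B", 1e-6, ["B0"]),
            pair("A", "C", 1e-2, ["B1"]),
            pair("B", "C", 1e-1, ["B2"]),
        ]
        m = cluster_crosstalk(pairs)
        rows = m.neg_log10_p.loc[["A", "B", "C"], ["A", "B", "C"]].to_numpy()
        # brute-force: first merge = closest row pair by Euclidean distance
        d = {
            (i, j): np.linalg.norm(rows[i] - rows[j])
            for i, j in itertools.combinations(range(3), 2)
        }
        first = min(d, key=d.get)
        assert set(m.linkage_matrix[0, :2].astype(int)) == set(first)
        assert m.linkage_matrix[0, 2] == pytest.approx(d[first])
        # complete linkage: second merge height = max distance to the pair
        rest = [k for k in range(3) if k not in first][0]
        expected = max(
            d[tuple(sorted((rest, first[0])))], d[tuple(sorted((rest, first[1])))]
        )
        assert m.linkage_matrix[1, 2] == pytest.approx(expected)

    def test_all_insignificant_matrix_single_cluster(self, caplog):
        pairs = [pair("A", "B", 1.0), pair("A", "C", 1.0), pair("B", "C", 1.0)]
        m = cluster_crosstalk(pairs)
        assert set(m.cluster_labels.values()) == {1}

    def test_newick_export_parses_with_all_leaves(self):
        pairs = [
            pair("A", "B", 1e-6, ["B0"]),
            pair("A", "C", 1e-2, ["B1"]),
            pair("B", "C", 1e-1, ["B2"]),
        ]
        m = cluster_crosstalk(pairs)
        nwk = linkage_to_newick(m.linkage_matrix, m.pathway_ids)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"A", "B", "C"}

    def test_planted_blocks_recovered(self, default_result):
        bundle, result, _ = default_result
        truth = bundle.truth
        labels = result.crosstalk_matrix.cluster_labels
        up = {labels[p] for p in truth.enriched_pathways_up}
        down = {labels[p] for p in truth.enriched_pathways_down}
        assert len(up) == 1 and len(down) == 1 and up != down


class TestKeyGenes:
    def setup(self):
        self.coll = [
            GeneSet("PW1", "", frozenset({"G1", "G2", "G3"})),
            GeneSet("PW2", "", frozenset({"G2", "G4"})),
        ]
        self.dys = [
            DysregulatedPathway("PW1", "down"),
            DysregulatedPathway("PW2", "down"),
        ]

    def test_inverse_condition_required(self):
        self.setup()
        # G1 down, targeted only by a down miRNA -> excluded
        cmap = cmap_from([("mir-d", "G1")])
        out = detect_key_genes(
            self.dys, self.coll, cmap,
            [], [rec("G1", "down")],
            [], [rec("mir-d", "down")],
        )
        assert out == []

    def test_non_de_gene_excluded(self):
        self.setup()
        cmap = cmap_from([("mir-u", "G1")])
        out = detect_key_genes(
            self.dys, self.coll, cmap, [], [], [rec("mir-u", "up")], []
        )
        assert out == []

    def test_qualifying_gene_and_mediator_flag(self):
        self.setup()
        cmap = cmap_from([("mir-u", "G2"), ("mir-u", "G1")])
        out = detect_key_genes(
            self.dys, self.coll, cmap,
            [], [rec("G1", "down"), rec("G2", "down")],
            [rec("mir-u", "up")], [],
        )
        by_gene = {k.gene: k for k in out}
        assert set(by_gene) == {"G1", "G2"}
        assert by_gene["G2"].is_mediator and not by_gene["G1"].is_mediator
        assert by_gene["G2"].pathways == {"PW1", "PW2"}

    def test_matches_brute_force_triple_condition_scan(self, default_result):
        bundle, result, _ = default_result
        cmap = result.consensus_map
        gene_dir = {r.feature_id: "up" for r in result.de_mrnas_up}
        gene_dir.update({r.feature_id: "down" for r in result.de_mrnas_down})
        mir_dir = {r.feature_id: "up" for r in result.de_mirnas_up}
        mir_dir.update({r.feature_id: "down" for r in result.de_mirnas_down})
        by_id = {gs.set_id: gs for gs in bundle.pathways}
        expected = set()
        for d in result.dysregulated:
            for g in by_id[d.pathway_id].genes:
                if g not in gene_dir:
                    continue
                for m, tset in cmap.targets.items():
                    if g in tset and m in mir_dir and mir_dir[m] != gene_dir[g]:
                        expected.add(g)
        assert {k.gene for k in result.key_genes} == expected

    def test_order_invariance(self):
        self.setup()
        cmap = cmap_from([("mir-u", "G2"), ("mir-u", "G1")])
        args = ([], [rec("G2", "down"), rec("G1", "down")], [rec("mir-u", "up")], [])
        a = detect_key_genes(self.dys, self.coll, cmap, *args)
        b = detect_key_genes(self.dys[::-1], self.coll[::-1], cmap, *args)
        assert [(k.gene, k.pathways) for k in a] == [(k.gene, k.pathways) for k in b]


class TestMediationFraction:
    def test_subset_in_every_pair_gives_one(self):
        pairs = [pair("A", "B", 0.01, ["G1"]), pair("A", "C", 0.01, ["G1", "G2"])]
        assert mediation_fraction(pairs, {"G1"}) == 1.0

    def test_disjoint_subset_gives_zero(self):
        pairs = [pair("A", "B", 0.01, ["G1"])]
        assert mediation_fraction(pairs, {"G9"}) == 0.0

    def test_four_of_five_gives_point_eight(self):
        pairs = [
            pair("A", "B", 0.01, ["M1"]),
            pair("A", "C", 0.01, ["M2"]),
            pair("B", "C", 0.01, ["M1", "X"]),
            pair("B", "D", 0.01, ["M2"]),
            pair("C", "D", 0.01, ["X"]),
        ]
        assert mediation_fraction(pairs, {"M1", "M2"}) == pytest.approx(0.8)

    def test_empty_pair_list_is_error(self):
        with pytest.raises(ValueError):
            mediation_fraction([], {"G1"})
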