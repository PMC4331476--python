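"""Synthetic-data generator: determinism, planted structure, calibration."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from mircross.pipeline import load_inputs
from mircross.synthetic import (
    SimParams,
    simulate_bundle,
    simulate_expression,
    simulate_mirna_loci,
    simulate_pathways,
    simulate_tool_predictions,
    write_bundle,
)

SMALL = dict(n_genes=400, n_mirnas=60, n_case=6, n_control=6,
             n_de_genes=40, n_de_mirnas_up=8, n_de_mirnas_down=8,
             n_pathways=10, n_regulators_up=6, n_regulators_down=2)


class TestExpression:
    def test_same_seed_bitwise_identical(self):
        a, am, at = simulate_expression(SimParams(**SMALL, seed=3))
        b, bm, bt = simulate_expression(SimParams(**SMALL, seed=3))
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(am.values, bm.values)
        assert at.de_mrnas_up == bt.de_mrnas_up

    def test_different_seeds_differ(self):
        a, _, _ = simulate_expression(SimParams(**SMALL, seed=3))
        b, _, _ = simulate_expression(SimParams(**SMALL, seed=4))
        assert not a.values.equals(b.values)

    def test_zero_effect_gives_empty_truth(self):
        _, _, truth = simulate_expression(SimParams(**SMALL, effect_log2=0.0))
        assert not truth.de_mrnas_up and not truth.de_mirnas_down

    def test_planted_mean_shift_matches_effect(self):
        # sample-mean oracle over replicates: planted |delta log2| ~= effect
        diffs = []
        for seed in range(3):
            p = SimParams(**SMALL, effect_log2=1.5, noise_sd=0.5,
                          array_bias_amp=0.0, seed=seed)
            mrna, _, truth = simulate_expression(p)
            case = mrna.values[mrna.case_samples].mean(axis=1)
            ctrl = mrna.values[mrna.control_samples].mean(axis=1)
            for g in truth.de_mrnas_up:
                diffs.append(case[g] - ctrl[g])
            for g in truth.de_mrnas_down:
                diffs.append(ctrl[g] - case[g])
        # SE of the mean over ~240 planted genes at noise 0.5, n=6+6
        assert np.mean(diffs) == pytest.approx(1.5, abs=0.06)

    def test_degenerate_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(n_genes=0)
        with pytest.raises(ValueError):
            SimParams(n_case=2)


class TestToolPredictions:
    def test_perfect_tools_report_exactly_truth(self):
        p = SimParams(**SMALL, tool_sensitivity=1.0, tool_fpr=0.0, seed=1)
        _, _, truth = simulate_expression(p)
        simulate_pathways(truth, p)
        table = simulate_tool_predictions(truth, p)
        true_pairs = {
            (m, g) for m, gs in truth.true_targets.items() for g in gs
        }
        got = set(zip(table["mirna"], table["gene"]))
        assert got == true_pairs
        counts = table.groupby(["mirna", "gene"])["tool"].nunique()
        assert (counts == p.tool_count).all()

    def test_zero_sensitivity_invalid_but_tiny_reports_nothing_true(self):
        p = SimParams(**SMALL, tool_sensitivity=1e-9, tool_fpr=0.0, seed=1)
        _, _, truth = simulate_expression(p)
        simulate_pathways(truth, p)
        assert simulate_tool_predictions(truth, p).empty

    def test_consensus_survival_matches_binomial_tail(self):
        # P(Bin(10, 0.8) >= 4) = 0.99877...
        expected = float(binom.sf(3, 10, 0.8))
        fracs = []
        for seed in range(3):
            p = SimParams(**SMALL, tool_sensitivity=0.8, tool_fpr=0.0, seed=seed)
            _, _, truth = simulate_expression(p)
            simulate_pathways(truth, p)
            table = simulate_tool_predictions(truth, p)
            counts = table.groupby(["mirna", "gene"])["tool"].nunique()
            n_true = sum(len(g) for g in truth.true_targets.values())
            fracs.append((counts >= 4).sum() / n_true)
        assert np.mean(fracs) == pytest.approx(expected, abs=0.01)


class TestPathwayStructure:
    def build(self, **kw):
        p = SimParams(**{**SMALL, **kw})
        _, _, truth = simulate_expression(p)
        coll, graphs = simulate_pathways(truth, p)
        return p, truth, coll, graphs

    def test_designated_pair_overlap_exactly_n_shared(self):
        p, truth, coll, _ = self.build(n_shared=5, seed=2)
        by_id = {gs.set_id: gs.genes for gs in coll}
        for a, b in truth.crosstalk_pairs:
            assert len(by_id[a] & by_id[b]) == p.n_shared

    def test_zero_shared_gives_zero_overlaps(self):
        _, truth, coll, _ = self.build(n_shared=0, seed=2)
        planted = truth.enriched_pathways_up + truth.enriched_pathways_down
        by_id = {gs.set_id: gs.genes for gs in coll}
        for a, b in itertools.combinations(planted, 2):
            assert not (by_id[a] & by_id[b])

    def test_cross_block_pathways_disjoint(self):
        _, truth, coll, _ = self.build(seed=2)
        by_id = {gs.set_id: gs.genes for gs in coll}
        for a in truth.enriched_pathways_up:
            for b in truth.enriched_pathways_down:
                assert not (by_id[a] & by_id[b])

    def test_planted_dense_neighborhood_within_k(self):
        p, truth, _, graphs = self.build(seed=2)
        for pid, dense in truth.planted_laps.items():
            g = graphs[pid].graph
            for a, b in itertools.combinations(dense, 2):
                assert nx.shortest_path_length(g, a, b) < p.lap_k
            # the remaining signature gene sits at distance >= k from all
            far = [x for x in truth.key_genes[pid] if x not in dense]
            for f in far:
                for d in dense:
                    assert nx.shortest_path_length(g, f, d) >= p.lap_k

    def test_clique_neighborhood_all_distance_one(self):
        _, truth, _, graphs = self.build(seed=3)
        pid, dense = next(iter(truth.planted_laps.items()))
        g = graphs[pid].graph
        assert all(
            g.has_edge(a, b) for a, b in itertools.combinations(dense, 2)
        )


class TestLoci:
    def test_planted_cluster_gaps_within_limit(self):
        p = SimParams(**SMALL, seed=4)
        _, _, truth = simulate_expression(p)
        simulate_pathways(truth, p)
        loci = simulate_mirna_loci(truth, p)
        by_id = {iv.feature_id: iv for iv in loci}
        for cluster in truth.mirna_clusters:
            ivs = sorted((by_id[m] for m in cluster), key=lambda x: x.start)
            assert len({x.chrom for x in ivs}) == 1
            for a, b in zip(ivs, ivs[1:]):
                assert b.start - a.end <= p.cluster_gap_bp

    def test_nonclustered_mirnas_are_far_apart(self):
        p = SimParams(**SMALL, seed=4)
        _, _, truth = simulate_expression(p)
        simulate_pathways(truth, p)
        loci = simulate_mirna_loci(truth, p)
        clustered = {m for c in truth.mirna_clusters for m in c}
        rest = [iv for iv in loci if iv.feature_id not in clustered]
        by_chrom = {}
        for iv in rest:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda x: x.start)
            for a, b in zip(ivs, ivs[1:]):
                assert b.start - a.end > p.cluster_gap_bp


class TestBundleRoundTrip:
    def test_writes_and_rereads_losslessly(self, tmp_path):
        p = SimParams(**SMALL, seed=6)
        bundle = simulate_bundle(p)
        write_bundle(bundle, tmp_path)
        mrna, mirna, preds, pathways, go_terms, graphs, loci = load_inputs(tmp_path)
        pd.testing.assert_frame_equal(
            mrna.values, bundle.mrna.values, check_names=False
        )
        assert mrna.group == bundle.mrna.group
        assert {g.set_id: g.genes for g in pathways} == {
            g.set_id: g.genes for g in bundle.pathways
        }
        assert {g.set_id: g.genes for g in go_terms} == {
            g.set_id: g.genes for g in bundle.go_terms
        }
        for pid, pg in bundle.graphs.items():
            assert graphs[pid].nodes == pg.nodes
            assert graphs[pid].edges == pg.edges
        assert sorted(loci, key=lambda x: x.feature_id) == sorted(
            bundle.mirna_loci, key=lambda x: x.feature_id
        )
        got_rows = set(map(tuple, preds[["mirna", "gene", "tool"]].to_numpy()))
        want_rows = set(
            map(tuple, bundle.predictions[["mirna", "gene", "tool"]].to_numpy())
        )
        assert got_rows == want_rows
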