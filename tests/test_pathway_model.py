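"""Pathway augmentation, clique statistic, permutation scoring, portions,
meta-pathways and the union-network discrepancy rule."""

import numpy as np
import pytest

from mircuits import (AnalysisConfig, PathwayGraph, augment_pathway,
                      build_meta_pathway, clique_statistic, fit_pathway,
                      pathway_significance, score_portions,
                      select_meta_elements, union_network)
from mircuits.datasets import MIRNA, NEGATIVE, NodeAnnotation, POSITIVE
from mircuits.pathway_model import PortionScore
from mircuits.priors import MIRNA_TARGET, build_prior
from mircuits.simulate import (make_chain_pathway,
                               simulate_pathway_cohort)

from conftest import make_dataset


def toy_pathway(edges, pathway_id="p"):
    p = PathwayGraph(pathway_id)
    for u, v in edges:
        p.add_edge(u, v)
    return p


class TestAugmentPathway:
    prior = build_prior([("mir1", "g1", MIRNA_TARGET),
                         ("mir1", "g2", MIRNA_TARGET),
                         ("mir1", "g3", MIRNA_TARGET),
                         ("mir1", "x1", MIRNA_TARGET),
                         ("mir1", "x2", MIRNA_TARGET),
                         ("mir2", "x9", MIRNA_TARGET)])

    def test_mirna_without_pathway_targets_not_added(self):
        p = toy_pathway([("g1", "g2")])
        out = augment_pathway(p, self.prior, {"mir2"})
        assert out.mirna_nodes() == set()

    def test_three_of_five_targets_in_pathway(self):
        p = toy_pathway([("g1", "g2"), ("g2", "g3")])
        out = augment_pathway(p, self.prior, {"mir1"})
        assert out.mirna_nodes() == {"mir1"}
        assert set(out.graph.successors("mir1")) == {"g1", "g2", "g3"}

    def test_unexpressed_mirna_not_added(self):
        p = toy_pathway([("g1", "g2")])
        out = augment_pathway(p, self.prior, set())
        assert out.mirna_nodes() == set()

    def test_gene_gene_topology_untouched(self):
        p = toy_pathway([("g1", "g2"), ("g3", "g2")])
        out = augment_pathway(p, self.prior, {"mir1", "mir2"})
        gene_edges = {(u, v) for u, v in out.graph.edges
                      if out.kind_of(u) != MIRNA}
        assert gene_edges == set(p.graph.edges)


class TestCliqueStatistic:
    def test_identical_class_submatrices_give_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 10))
        assert clique_statistic(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_matches_univariate_closed_form(self):
        rng = np.random.default_rng(1)
        xp = rng.normal(0.0, 1.0, size=(1, 40))
        xn = rng.normal(0.8, 1.2, size=(1, 40))
        got = clique_statistic(xp, xn, ridge=0.0)
        # closed-form 1-D Gaussian LRT with MLE variances
        x = np.hstack([xp, xn]).ravel()
        n, n1, n2 = x.size, xp.size, xn.size
        expected = (n * np.log(x.var())
                    - n1 * np.log(xp.var()) - n2 * np.log(xn.var()))
        assert got == pytest.approx(expected, abs=1e-6)

    def test_monotone_in_mean_shift(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(1, 500))
        stats = [clique_statistic(base + delta,
                                  rng.normal(size=(1, 500)))
                 for delta in (0.0, 0.5, 1.0, 2.0)]
        assert stats == sorted(stats)

    def test_invariant_to_within_class_sample_order(self):
        rng = np.random.default_rng(3)
        xp = rng.normal(size=(2, 15))
        xn = rng.normal(0.4, 1.0, size=(2, 15))
        perm = rng.permutation(15)
        assert clique_statistic(xp, xn) == pytest.approx(
            clique_statistic(xp[:, perm], xn[:, perm]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 3 samples"):
            clique_statistic(np.zeros((1, 2)), np.zeros((1, 5)))


def _cohort_for(pathways, seed, effect=0.0, signal_nodes=None, n=30):
    sig_id = pathways[0].pathway_id if signal_nodes else None
    gene_ds, mirna_ds, _ = simulate_pathway_cohort(
        pathways, sig_id, signal_nodes, effect=effect,
        n_pos=n // 2, n_neg=n - n // 2, seed=seed)
    return gene_ds, mirna_ds


class TestPathwaySignificance:
    def test_minimum_attainable_p(self, cfg):
        pw = make_chain_pathway("pw", 3, 3)
        nodes = sorted(pw.gene_nodes())
        gene_ds, mirna_ds = _cohort_for([pw], seed=0, effect=3.0,
                                        signal_nodes=set(nodes), n=60)
        p = pathway_significance(pw, mirna_ds, gene_ds, cfg,
                                 n_permutations=99)
        assert p == pytest.approx(1.0 / 100.0)

    def test_sparse_overlap_skipped(self, cfg):
        pw = toy_pathway([("zz1", "zz2")])
        gene_ds = make_dataset(np.random.default_rng(0).normal(
            8, 1, (2, 12)), features=["a", "zz1"])
        mirna_ds = make_dataset(np.empty((0, 12)), features=[],
                                classes=list(gene_ds.classes))
        assert pathway_significance(pw, mirna_ds, gene_ds, cfg,
                                    n_permutations=20) is None

    def test_null_p_values_never_zero_and_superuniform(self, cfg):
        pw = make_chain_pathway("pw", 3, 3)
        ps = []
        for seed in range(40):
            gene_ds, mirna_ds = _cohort_for([pw], seed=seed, n=24)
            p = pathway_significance(
                pw, mirna_ds, gene_ds, cfg.replace(rng_seed=seed),
                n_permutations=99)
            ps.append(p)
        ps = np.array(ps)
        assert (ps > 0).all()
        # rejection at alpha=0.2 should be near-nominal under the null
        assert abs((ps <= 0.2).mean() - 0.2) < 0.2


class TestScorePortions:
    def test_single_clique_pathway_single_portion(self, cfg):
        pw = toy_pathway([("a", "b")])
        gene_ds, mirna_ds = _cohort_for([pw], seed=1, n=20)
        fit = fit_pathway(pw, mirna_ds, gene_ds, cfg, n_permutations=50)
        portions = score_portions(fit, cfg)
        assert len(portions) == 1
        assert portions[0].nodes == frozenset({"a", "b"})

    def test_percentile_one_returns_all_paths(self, cfg):
        pw = make_chain_pathway("pw", 4, 3)
        gene_ds, mirna_ds = _cohort_for([pw], seed=2, n=20)
        fit = fit_pathway(pw, mirna_ds, gene_ds, cfg, n_permutations=50)
        all_paths = list(fit.jtree.simple_paths(cfg.portion_length_cap))
        portions = score_portions(fit, cfg, percentile=1.0)
        assert len(portions) == len(all_paths)

    def test_signal_localizes_to_planted_cliques(self, cfg):
        hits = 0
        for seed in range(10):
            pw = make_chain_pathway("pw", 5, 4)
            nodes = sorted(pw.gene_nodes())
            # design cliques 1-2 (0-based): nodes 4..9 away from borders
            signal = set(nodes[4:10])
            gene_ds, mirna_ds = _cohort_for([pw], seed=seed, effect=1.5,
                                            signal_nodes=signal, n=100)
            fit = fit_pathway(pw, mirna_ds, gene_ds,
                              cfg.replace(rng_seed=seed),
                              n_permutations=200)
            best = score_portions(fit, cfg)[0]
            hits += signal <= set(best.nodes)
        assert hits >= 9


class TestMetaPathway:
    def _portion(self, pathway_id, nodes):
        return PortionScore(pathway_id, (0,), frozenset(nodes), 1.0, 0.5)

    def test_disjoint_portions_disconnect(self):
        p1 = toy_pathway([("a", "b")], "p1")
        p2 = toy_pathway([("c", "d")], "p2")
        meta = build_meta_pathway([self._portion("p1", {"a", "b"}),
                                   self._portion("p2", {"c", "d"})],
                                  [p1, p2])
        assert meta.graph.number_of_nodes() == 4
        assert meta.graph.number_of_edges() == 2

    def test_shared_gene_bridges_portions(self):
        p1 = toy_pathway([("a", "g")], "p1")
        p2 = toy_pathway([("g", "b")], "p2")
        meta = build_meta_pathway([self._portion("p1", {"a", "g"}),
                                   self._portion("p2", {"g", "b"})],
                                  [p1, p2])
        assert meta.graph.number_of_nodes() == 3
        assert set(meta.graph.successors("a")) == {"g"}
        assert set(meta.graph.successors("g")) == {"b"}

    def test_empty_portion_list_empty_graph(self):
        meta = build_meta_pathway([], [])
        assert meta.graph.number_of_nodes() == 0

    def test_selection_is_subset_of_meta_nodes(self, cfg):
        pw = make_chain_pathway("pw", 4, 4)
        nodes = sorted(pw.gene_nodes())
        gene_ds, mirna_ds = _cohort_for([pw], seed=3, effect=1.0,
                                        signal_nodes=set(nodes[3:8]),
                                        n=40)
        fit = fit_pathway(pw, mirna_ds, gene_ds, cfg, n_permutations=100)
        meta = build_meta_pathway(score_portions(fit, cfg), [pw])
        selected = select_meta_elements(meta, mirna_ds, gene_ds, cfg,
                                        n_permutations=100)
        assert selected <= set(meta.graph.nodes)

    def test_single_clique_meta_selects_all_nodes(self, cfg):
        meta = toy_pathway([("a", "b"), ("b", "c"), ("a", "c")], "meta")
        gene_ds, mirna_ds = _cohort_for([meta], seed=4, n=20)
        selected = select_meta_elements(meta, mirna_ds, gene_ds, cfg,
                                        n_permutations=50)
        assert selected == {"a", "b", "c"}


class TestUnionNetwork:
    def _ann(self, node, lr, cohort):
        return NodeAnnotation(node, "gene", lr, cohort)

    def _run(self, lr_a, lr_b, cfg=None):
        cfg = cfg or AnalysisConfig()
        meta = toy_pathway([("x", "y")], "m")
        ann_a = {n: self._ann(n, lr_a, "A") for n in ("x", "y")}
        ann_b = {n: self._ann(n, lr_b, "B") for n in ("x", "y")}
        return union_network({"x", "y"}, {"x", "y"}, meta, meta,
                             ann_a, ann_b, cfg)

    def test_concordant_node_colored_with_reference_value(self):
        net = self._run(0.5, 0.5)
        assert net.nodes["x"]["display_state"] == "colored"
        assert net.nodes["x"]["log2ratio"] == pytest.approx(0.5)

    def test_small_discordance_kept_neutral(self):
        net = self._run(0.04, -0.04)
        assert net.nodes["x"]["display_state"] == "neutral"

    def test_large_discordance_discarded(self):
        net = self._run(0.3, -0.3)
        assert net.n_nodes() == 0

    def test_difference_mode_discards_on_distance(self):
        cfg = AnalysisConfig(discrepancy_mode="difference")
        net = self._run(0.5, 0.3, cfg)  # concordant but d = 0.2 > 0.1
        assert net.n_nodes() == 0

    def test_missing_annotation_discards_node(self):
        meta = toy_pathway([("x", "y")], "m")
        ann_a = {"x": self._ann("x", 0.2, "A"),
                 "y": self._ann("y", 0.2, "A")}
        ann_b = {"x": self._ann("x", 0.2, "B")}
        net = union_network({"x", "y"}, {"x"}, meta, meta, ann_a, ann_b,
                            AnalysisConfig())
        assert set(net.nodes) == {"x"}

    def test_edges_restricted_to_survivors(self):
        meta = toy_pathway([("x", "y"), ("y", "z")], "m")
        ann_a = {n: self._ann(n, 0.2, "A") for n in "xyz"}
        ann_b = {n: self._ann(n, 0.2, "B") for n in "xy"}
        net = union_network(set("xyz"), set("xyz"), meta, meta, ann_a,
                            ann_b, AnalysisConfig())
        assert set(net.nodes) == {"x", "y"}
        assert list(net.edges) == [("x", "y")]
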