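"""Mixed-circuit inference against brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest

from mircuits import (AnalysisConfig, binary_relations,
                      circuits_to_network, find_mixed_circuits,
                      prior_correlations)
from mircuits.circuits import (CorrelationEdge, MIRNA_INHIBITS_BOTH,
                               MixedCircuit, TF_ACTIVATES_BOTH)
from mircuits.datasets import NEGATIVE, POSITIVE
from mircuits.priors import (InteractionPrior, MIRNA_TARGET, PriorEdge,
                             TF_GENE, TF_MIRNA, build_prior)

from conftest import make_dataset


def _pair_datasets(mirna_rows, gene_rows, n):
    classes = [POSITIVE] * (n // 2) + [NEGATIVE] * (n - n // 2)
    mirna_ds = make_dataset(
        np.array([mirna_rows[k] for k in sorted(mirna_rows)]),
        features=sorted(mirna_rows), classes=classes)
    gene_ds = make_dataset(
        np.array([gene_rows[k] for k in sorted(gene_rows)]),
        features=sorted(gene_rows), classes=classes)
    return mirna_ds, gene_ds


class TestPriorCorrelations:
    def test_identical_and_negated_profiles(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        mirna_ds, gene_ds = _pair_datasets({"m1": x}, {"g1": x,
                                                       "g2": -x}, 4)
        prior = build_prior([("m1", "g1", MIRNA_TARGET),
                             ("m1", "g2", MIRNA_TARGET)])
        edges = {(e.target, round(e.r, 9))
                 for e in prior_correlations(mirna_ds, gene_ds, prior)}
        assert edges == {("g1", 1.0), ("g2", -1.0)}

    def test_hand_computed_correlation(self):
        # cov = 3/4 per sample convention; r = 3 / sqrt(5*5) = 0.6
        mirna_ds, gene_ds = _pair_datasets(
            {"m1": np.array([1.0, 2.0, 3.0, 4.0])},
            {"g1": np.array([2.0, 1.0, 4.0, 3.0])}, 4)
        prior = build_prior([("m1", "g1", MIRNA_TARGET)])
        (edge,) = prior_correlations(mirna_ds, gene_ds, prior)
        assert edge.r == pytest.approx(0.6)
        assert edge.n == 4

    def test_mismatched_samples_rejected(self):
        a = make_dataset(np.zeros((1, 4)))
        b = make_dataset(np.zeros((1, 4)))
        b.samples[0] = "other"
        with pytest.raises(ValueError, match="sample list"):
            prior_correlations(a, b, build_prior([]))

    def test_zero_variance_profile_skipped(self):
        mirna_ds, gene_ds = _pair_datasets(
            {"m1": np.array([5.0, 5.0, 5.0, 5.0])},
            {"g1": np.array([1.0, 2.0, 3.0, 4.0])}, 4)
        prior = build_prior([("m1", "g1", MIRNA_TARGET)])
        assert prior_correlations(mirna_ds, gene_ds, prior) == set()


class TestBinaryRelations:
    @pytest.mark.parametrize("r,kept", [
        (-0.41, True), (-0.4, True), (-0.39, False), (0.9, False),
    ])
    def test_anticorrelation_threshold(self, r, kept):
        edge = CorrelationEdge("m", "g", MIRNA_TARGET, r=r, n=10)
        out = binary_relations({edge}, 0.4)
        assert (edge in out) is kept

    def test_positive_switch_matches_brute_force(self):
        rng = np.random.default_rng(0)
        edges = {CorrelationEdge(f"m{i}", f"g{i}", MIRNA_TARGET,
                                 r=float(r), n=20)
                 for i, r in enumerate(rng.uniform(-1, 1, 50))}
        out = binary_relations(edges, 0.4, allow_positive=True)
        brute = {e for e in edges if abs(e.r) >= 0.4}
        assert out == brute

    def test_non_mirna_relations_excluded(self):
        edge = CorrelationEdge("tf", "g", TF_GENE, r=-0.9, n=10)
        assert binary_relations({edge}, 0.4) == set()


def brute_force_circuits(mirna_ds, gene_ds, prior, threshold):
    """Independent oracle: test every (tf, mirna, gene) triple directly."""

    def r(a, b):
        xa = mirna_ds.row(a) if a in mirna_ds else gene_ds.row(a)
        xb = mirna_ds.row(b) if b in mirna_ds else gene_ds.row(b)
        if xa.std() == 0 or xb.std() == 0:
            return None
        return float(np.corrcoef(xa, xb)[0, 1])

    pairs = {k: prior.pairs(k) for k in (TF_MIRNA, TF_GENE, MIRNA_TARGET)}
    everything = set(mirna_ds.features) | set(gene_ds.features)
    found = set()
    for tf, mirna, gene in itertools.permutations(everything, 3):
        if ((tf, mirna) in pairs[TF_MIRNA]
                and (tf, gene) in pairs[TF_GENE]
                and (mirna, gene) in pairs[MIRNA_TARGET]):
            r1, r2 = r(tf, mirna), r(tf, gene)
            if r1 is not None and r2 is not None \
                    and r1 >= threshold and r2 >= threshold:
                found.add((TF_ACTIVATES_BOTH, tf, mirna, gene))
        if ((mirna, tf) in pairs[MIRNA_TARGET]
                and (mirna, gene) in pairs[MIRNA_TARGET]
                and (tf, gene) in pairs[TF_GENE]):
            r1, r2 = r(mirna, tf), r(mirna, gene)
            if r1 is not None and r2 is not None \
                    and r1 <= -threshold and r2 <= -threshold:
                found.add((MIRNA_INHIBITS_BOTH, tf, mirna, gene))
    return found


def _random_instance(rng, n_mirna=4, n_gene=8, n_samples=12,
                     edge_range=(5, 25)):
    mirnas = [f"m{i}" for i in range(n_mirna)]
    genes = [f"g{i}" for i in range(n_gene)]
    classes = [POSITIVE] * (n_samples // 2) + \
        [NEGATIVE] * (n_samples - n_samples // 2)
    mirna_ds = make_dataset(rng.normal(8, 1, (n_mirna, n_samples)),
                            features=mirnas, classes=classes)
    gene_ds = make_dataset(rng.normal(8, 1, (n_gene, n_samples)),
                           features=genes, classes=classes)
    edges = set()
    for _ in range(rng.integers(*edge_range)):
        kind = rng.choice([MIRNA_TARGET, TF_GENE, TF_MIRNA])
        if kind == MIRNA_TARGET:
            reg, tgt = rng.choice(mirnas), rng.choice(genes)
        elif kind == TF_GENE:
            reg, tgt = rng.choice(genes), rng.choice(genes)
        else:
            reg, tgt = rng.choice(genes), rng.choice(mirnas)
        if reg != tgt:
            edges.add(PriorEdge(str(reg), str(tgt), str(kind)))
    return mirna_ds, gene_ds, InteractionPrior(edges)


class TestFindMixedCircuits:
    def test_empty_prior_gives_no_circuits(self, toy_dataset):
        mirna_ds, gene_ds, _ = _random_instance(np.random.default_rng(0))
        out = find_mixed_circuits(mirna_ds, gene_ds,
                                  InteractionPrior(set()))
        assert out == []

    def test_matches_exhaustive_enumeration(self, cfg):
        rng = np.random.default_rng(2024)
        checked_nonempty = 0
        for _ in range(40):
            mirna_ds, gene_ds, prior = _random_instance(rng)
            fast = {c.key for c in find_mixed_circuits(
                mirna_ds, gene_ds, prior,
                cfg.replace(circuit_corr_threshold=0.2))}
            brute = brute_force_circuits(mirna_ds, gene_ds, prior, 0.2)
            assert fast == brute
            checked_nonempty += bool(brute)
        assert checked_nonempty > 0

    def test_subthreshold_edge_rejected(self):
        # tf->mirna correlation deliberately just below 0.2
        n = 200
        rng = np.random.default_rng(5)
        tf = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        mirna = 0.19 * tf + np.sqrt(1 - 0.19 ** 2) * noise
        r_emp = np.corrcoef(tf, mirna)[0, 1]
        gene = tf.copy() + 1e-3 * rng.standard_normal(n)
        classes = [POSITIVE] * 100 + [NEGATIVE] * 100
        mirna_ds = make_dataset(mirna[None, :] + 8, features=["m"],
                                classes=classes)
        gene_ds = make_dataset(np.vstack([tf, gene]) + 8,
                               features=["tf", "g"], classes=classes)
        prior = build_prior([("tf", "m", TF_MIRNA),
                             ("tf", "g", TF_GENE),
                             ("m", "g", MIRNA_TARGET)])
        cfg = AnalysisConfig(circuit_corr_threshold=max(0.2, r_emp + 1e-6))
        assert find_mixed_circuits(mirna_ds, gene_ds, prior, cfg) == []

    def test_invariant_to_feature_and_sample_permutation(self, cfg):
        rng = np.random.default_rng(77)
        mirna_ds, gene_ds, prior = _random_instance(rng)
        base = {c.key for c in find_mixed_circuits(mirna_ds, gene_ds,
                                                   prior, cfg)}
        perm = rng.permutation(mirna_ds.n_samples)
        fperm = rng.permutation(gene_ds.n_features)

        def shuffle(ds, feat_perm=None):
            feats = ds.features if feat_perm is None else \
                [ds.features[i] for i in feat_perm]
            vals = ds.values if feat_perm is None else ds.values[feat_perm]
            return make_dataset(vals[:, perm], features=feats,
                                classes=[ds.classes[i] for i in perm])

        shuffled = {c.key for c in find_mixed_circuits(
            shuffle(mirna_ds), shuffle(gene_ds, fperm), prior, cfg)}
        assert shuffled == base

    def test_raising_threshold_never_adds_circuits(self, cfg):
        rng = np.random.default_rng(123)
        mirna_ds, gene_ds, prior = _random_instance(rng, n_samples=16)
        lo = {c.key for c in find_mixed_circuits(
            mirna_ds, gene_ds, prior,
            cfg.replace(circuit_corr_threshold=0.1))}
        hi = {c.key for c in find_mixed_circuits(
            mirna_ds, gene_ds, prior,
            cfg.replace(circuit_corr_threshold=0.4))}
        assert hi <= lo


class TestCircuitsToNetwork:
    def _circuit(self, tf="tf", mirna="m", gene="g"):
        return MixedCircuit(TF_ACTIVATES_BOTH, tf, mirna, gene,
                            r_tf_mirna=0.8, r_tf_gene=0.7,
                            r_mirna_gene=0.56)

    def test_single_circuit_three_nodes_three_edges(self):
        net = circuits_to_network([self._circuit()])
        assert net.n_nodes() == 3 and net.n_edges() == 3

    def test_shared_edge_deduplicated(self):
        # set-union oracle: nodes {tf, m, g1, g2}; edges tf->m (shared,
        # counted once), tf->g1, m->g1, tf->g2, m->g2
        net = circuits_to_network([self._circuit(gene="g1"),
                                   self._circuit(gene="g2")])
        assert set(net.nodes) == {"tf", "m", "g1", "g2"}
        assert net.n_edges() == 5

    def test_empty_input_empty_network(self):
        net = circuits_to_network([])
        assert net.n_nodes() == 0 and net.n_edges() == 0

    def test_dedup_keeps_largest_magnitude(self):
        a = self._circuit(gene="g1")
        b = MixedCircuit(TF_ACTIVATES_BOTH, "tf", "m", "g2",
                         r_tf_mirna=0.95, r_tf_gene=0.7,
                         r_mirna_gene=0.5)
        net = circuits_to_network([a, b])
        assert net.edges["tf", "m"]["weight"] == pytest.approx(0.95)
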