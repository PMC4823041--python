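"""Synthetic two-cohort miRNA/mRNA study generator with planted truth.

Emulates the structure of the motivating two-cohort myeloma study: two
classes per cohort (translocation-positive vs -negative), hundreds of
miRNA and thousands of gene features on a log2 scale, target-prediction
priors diluted with decoy edges, and pathway graphs with one
class-dependent signal pathway among decoys.  Every planted element is
recorded in a :class:`SimulationTruth` so downstream inference can be
scored against a known answer.

Background features are independent Gaussians on the log2 scale with
per-feature baselines; planted circuit members are drawn from an exact
trivariate correlation matrix (rejected before sampling when the
requested correlations are not jointly realisable); pathway cohorts are
drawn from a graph-consistent multivariate Gaussian whose precision
matrix is supported on the moral graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .circuits import (MIRNA_INHIBITS_BOTH, MixedCircuit,
                       TF_ACTIVATES_BOTH)
from .cliquetree import moralize
from .datasets import ExpressionDataset, GENE, MIRNA, NEGATIVE, POSITIVE, TF
from .pathways import PathwayGraph
from .priors import (InteractionPrior, MIRNA_TARGET, PriorEdge, TF_GENE,
                     TF_MIRNA)


@dataclass(frozen=True)
class PlantedCircuit:
    """A mixed circuit planted in the generator with target correlations."""

    topology: str
    tf: str
    mirna: str
    gene: str
    r_tf_mirna: float
    r_tf_gene: float
    r_mirna_gene: float

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.topology, self.tf, self.mirna, self.gene)

    def correlation_matrix(self) -> np.ndarray:
        """3x3 target correlation over (tf, mirna, gene)."""
        r = np.array([
            [1.0, self.r_tf_mirna, self.r_tf_gene],
            [self.r_tf_mirna, 1.0, self.r_mirna_gene],
            [self.r_tf_gene, self.r_mirna_gene, 1.0],
        ])
        return r

    def prior_edges(self) -> set[PriorEdge]:
        if self.topology == TF_ACTIVATES_BOTH:
            return {
                PriorEdge(self.tf, self.mirna, TF_MIRNA),
                PriorEdge(self.tf, self.gene, TF_GENE),
                PriorEdge(self.mirna, self.gene, MIRNA_TARGET),
            }
        return {
            PriorEdge(self.mirna, self.tf, MIRNA_TARGET),
            PriorEdge(self.mirna, self.gene, MIRNA_TARGET),
            PriorEdge(self.tf, self.gene, TF_GENE),
        }


@dataclass
class SimulationTruth:
    """Ground truth of one simulated study."""

    circuits: list[PlantedCircuit] = field(default_factory=list)
    binary_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    signal_pathway_id: str | None = None
    signal_nodes: frozenset[str] = frozenset()
    effect_size: float = 0.0

    def circuit_keys(self) -> set[tuple[str, str, str, str]]:
        return {c.key for c in self.circuits}


def default_plants(n_tf_apex: int = 3, n_mirna_apex: int = 3,
                   strength: float = 0.7,
                   strength_range: tuple[float, float] | None = None,
                   rng: np.random.Generator | None = None,
                   ) -> list[PlantedCircuit]:
    """Standard plant specification with self-consistent correlations.

    The two apex edges get the requested strength (positive for the TF
    apex, negative for the miRNA apex) and the closing edge the product
    of the two, which keeps the implied covariance positive definite for
    any strength < 1.
    """
    rng = rng or np.random.default_rng(0)
    plants: list[PlantedCircuit] = []

    def draw() -> float:
        if strength_range is None:
            return strength
        lo, hi = strength_range
        return float(rng.uniform(lo, hi))

    for i in range(n_tf_apex):
        s1, s2 = draw(), draw()
        plants.append(PlantedCircuit(
            TF_ACTIVATES_BOTH, f"TFP{i:03d}", f"mir-P{i:03d}",
            f"GENEP{i:04d}", r_tf_mirna=s1, r_tf_gene=s2,
            r_mirna_gene=s1 * s2))
    for i in range(n_mirna_apex):
        s1, s2 = draw(), draw()
        plants.append(PlantedCircuit(
            MIRNA_INHIBITS_BOTH, f"TFQ{i:03d}", f"mir-Q{i:03d}",
            f"GENEQ{i:04d}", r_tf_mirna=-s1, r_tf_gene=s1 * s2,
            r_mirna_gene=-s2))
    return plants


def _baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.uniform(6.0, 10.0, size=n)


def simulate_cohort(n_samples: int = 96, n_mirna: int = 300,
                    n_gene: int = 2000,
                    circuits: list[PlantedCircuit] | None = None,
                    n_binary: int = 0, binary_strength: float = 0.7,
                    decoy_factor: int = 10, positive_fraction: float = 0.14,
                    cohort_id: str = "cohortA", seed: int = 0,
                    ) -> tuple[ExpressionDataset, ExpressionDataset,
                               InteractionPrior, SimulationTruth]:
    """Simulate one cohort's paired matrices, prior and truth.

    Planted circuit members are sampled from the exact trivariate
    Gaussian implied by each plant's correlation targets (a failure is
    raised before sampling if a target matrix is not positive definite).
    Background features are independent, with log2-scale spreads drawn
    below the planted spread so variance filtering never removes planted
    members.  The prior holds every planted relation plus
    ``decoy_factor`` times as many decoy edges among background features,
    mimicking the low precision of target predictions.
    """
    rng = np.random.default_rng(seed)
    circuits = list(circuits) if circuits is not None else []

    for plant in circuits:
        try:
            np.linalg.cholesky(plant.correlation_matrix())
        except np.linalg.LinAlgError:
            raise ValueError(
                f"unsatisfiable correlation targets for planted circuit "
                f"{plant.key}") from None

    planted_mirnas = [c.mirna for c in circuits]
    planted_tfs = [c.tf for c in circuits]
    planted_genes = [c.gene for c in circuits]
    binary_pairs = [(f"mir-X{i:03d}", f"GENEX{i:04d}",
                     -abs(binary_strength)) for i in range(n_binary)]

    mirna_ids = planted_mirnas + [m for m, _g, _r in binary_pairs]
    mirna_ids += [f"mir-B{i:04d}" for i in
                  range(max(0, n_mirna - len(mirna_ids)))]
    gene_ids = planted_tfs + planted_genes + [g for _m, g, _r
                                              in binary_pairs]
    gene_ids += [f"GENEB{i:05d}" for i in
                 range(max(0, n_gene - len(gene_ids)))]
    samples = [f"{cohort_id}_s{i:04d}" for i in range(n_samples)]
    n_pos = max(3, int(round(positive_fraction * n_samples)))
    classes = [POSITIVE] * n_pos + [NEGATIVE] * (n_samples - n_pos)

    # standard-normal signal layer, then per-feature scale and baseline
    mirna_z = {}
    gene_z = {}
    for plant in circuits:
        chol = np.linalg.cholesky(plant.correlation_matrix())
        tri = chol @ rng.standard_normal((3, n_samples))
        gene_z[plant.tf] = tri[0]
        mirna_z[plant.mirna] = tri[1]
        gene_z[plant.gene] = tri[2]
    for mirna, gene, r in binary_pairs:
        m = rng.standard_normal(n_samples)
        g = r * m + np.sqrt(1.0 - r * r) * rng.standard_normal(n_samples)
        mirna_z[mirna] = m
        gene_z[gene] = g

    def build_matrix(ids: list[str], planted: dict[str, np.ndarray],
                     ) -> np.ndarray:
        out = np.empty((len(ids), n_samples))
        for i, fid in enumerate(ids):
            if fid in planted:
                out[i] = planted[fid]          # planted spread: 1.0
            else:
                sd = rng.uniform(0.5, 0.9)
                out[i] = sd * rng.standard_normal(n_samples)
        return out + _baseline(rng, len(ids))[:, None]

    mirna_values = build_matrix(mirna_ids, mirna_z)
    gene_values = build_matrix(gene_ids, gene_z)

    kinds = {m: MIRNA for m in mirna_ids}
    kinds.update({g: GENE for g in gene_ids})
    kinds.update({t: TF for t in planted_tfs})

    mirna_ds = ExpressionDataset(cohort_id, mirna_ids, samples,
                                 mirna_values, classes,
                                 {m: MIRNA for m in mirna_ids})
    gene_ds = ExpressionDataset(cohort_id, gene_ids, samples, gene_values,
                                classes, {g: kinds[g] for g in gene_ids})

    # prior: planted relations plus decoys among background features
    edges: set[PriorEdge] = set()
    for plant in circuits:
        edges |= plant.prior_edges()
    for mirna, gene, _r in binary_pairs:
        edges.add(PriorEdge(mirna, gene, MIRNA_TARGET))
    n_decoys = decoy_factor * max(len(edges), 1)
    bg_mirnas = [m for m in mirna_ids if m not in mirna_z]
    bg_genes = [g for g in gene_ids if g not in gene_z]
    decoy_tfs = bg_genes[: max(2, len(bg_genes) // 50)]
    existing = {(e.regulator, e.target, e.relation) for e in edges}
    attempts = 0
    while len(edges) - len(existing) < n_decoys and attempts < 50 * n_decoys:
        attempts += 1
        kind = rng.choice([MIRNA_TARGET, TF_GENE, TF_MIRNA])
        if kind == MIRNA_TARGET and bg_mirnas and bg_genes:
            e = PriorEdge(str(rng.choice(bg_mirnas)),
                          str(rng.choice(bg_genes)), MIRNA_TARGET)
        elif kind == TF_GENE and decoy_tfs and bg_genes:
            tf, g = str(rng.choice(decoy_tfs)), str(rng.choice(bg_genes))
            if tf == g:
                continue
            e = PriorEdge(tf, g, TF_GENE)
        elif kind == TF_MIRNA and decoy_tfs and bg_mirnas:
            e = PriorEdge(str(rng.choice(decoy_tfs)),
                          str(rng.choice(bg_mirnas)), TF_MIRNA)
        else:
            continue
        edges.add(e)
    prior = InteractionPrior(edges)

    truth = SimulationTruth(circuits=circuits,
                            binary_pairs=binary_pairs)
    return mirna_ds, gene_ds, prior, truth


# -- pathway simulation ----------------------------------------------------

def make_chain_pathway(pathway_id: str, n_cliques: int = 5,
                       clique_size: int = 4) -> PathwayGraph:
    """A pathway whose junction tree is a chain of overlapping cliques.

    Consecutive cliques share exactly one gene; edges are oriented from
    lower- to higher-indexed nodes so moralization recovers each clique.
    """
    p = PathwayGraph(pathway_id)
    n_nodes = n_cliques * (clique_size - 1) + 1
    names = [f"{pathway_id}_n{k:02d}" for k in range(n_nodes)]
    for c in range(n_cliques):
        start = c * (clique_size - 1)
        members = names[start:start + clique_size]
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                p.add_edge(u, v)
    return p


def make_random_dag_pathway(pathway_id: str, n_nodes: int,
                            edge_prob: float,
                            rng: np.random.Generator) -> PathwayGraph:
    """Random DAG pathway: ordered pairs wired with fixed probability."""
    p = PathwayGraph(pathway_id)
    names = [f"{pathway_id}_n{k:02d}" for k in range(n_nodes)]
    for n in names:
        p.add_gene(n)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                p.add_edge(names[i], names[j])
    return p


def _graph_covariance(pathway: PathwayGraph, coupling: float = 0.3,
                      ) -> tuple[list[str], np.ndarray]:
    """Correlation matrix whose precision is supported on the moral graph.

    The precision matrix is a diagonally dominant M-matrix (unit diagonal
    plus degree-weighted slack), hence positive definite; its inverse is
    normalized to unit variances.
    """
    nodes = sorted(pathway.gene_nodes())
    idx = {n: i for i, n in enumerate(nodes)}
    moral = moralize(pathway.graph.subgraph(nodes))
    k = len(nodes)
    prec = np.eye(k)
    for u, v in moral.edges:
        prec[idx[u], idx[v]] = prec[idx[v], idx[u]] = -coupling
    deg = (prec != 0).sum(axis=1) - 1
    prec[np.diag_indices(k)] = 1.0 + coupling * deg
    cov = np.linalg.inv(prec)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    return nodes, corr


def simulate_pathway_cohort(pathways: list[PathwayGraph],
                            signal_pathway_id: str | None,
                            signal_nodes: set[str] | None = None,
                            effect: float = 1.5, n_pos: int = 50,
                            n_neg: int = 50, cohort_id: str = "cohortA",
                            seed: int = 0,
                            mirna_targets: dict[str, set[str]]
                            | None = None, mirna_coupling: float = 0.6,
                            ) -> tuple[ExpressionDataset,
                                       ExpressionDataset,
                                       SimulationTruth]:
    """Graph-consistent Gaussian expression with a planted class shift.

    Gene expression for each pathway is drawn from a multivariate normal
    whose precision matrix lives on the pathway's moral graph;
    positive-class samples get an ``effect``-SD mean shift on the signal
    nodes.  Optional miRNAs are generated as noisy negatives of the mean
    of their target genes, so pathway augmentation has matching
    expression rows.
    """
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    samples = [f"{cohort_id}_s{i:04d}" for i in range(n)]
    classes = [POSITIVE] * n_pos + [NEGATIVE] * n_neg
    signal_nodes = set(signal_nodes or ())

    gene_ids: list[str] = []
    blocks: list[np.ndarray] = []
    for pw in pathways:
        nodes, corr = _graph_covariance(pw)
        chol = np.linalg.cholesky(corr)
        z = chol @ rng.standard_normal((len(nodes), n))
        if pw.pathway_id == signal_pathway_id and signal_nodes:
            shift = np.array([effect if node in signal_nodes else 0.0
                              for node in nodes])
            z[:, :n_pos] += shift[:, None]
        gene_ids.extend(nodes)
        blocks.append(z)
    gene_z = np.vstack(blocks) if blocks else np.empty((0, n))
    gene_values = gene_z + _baseline(rng, len(gene_ids))[:, None]
    gene_ds = ExpressionDataset(cohort_id, gene_ids, samples, gene_values,
                                classes, {g: GENE for g in gene_ids})

    mirna_targets = mirna_targets or {}
    mirna_ids = sorted(mirna_targets)
    mirna_rows = []
    for m in mirna_ids:
        targets = sorted(t for t in mirna_targets[m] if t in gene_ds)
        if targets:
            base = np.mean([gene_ds.row(t) - gene_ds.row(t).mean()
                            for t in targets], axis=0)
            sd = base.std() or 1.0
            row = (-mirna_coupling * base / sd
                   + np.sqrt(1 - mirna_coupling ** 2)
                   * rng.standard_normal(n))
        else:
            row = rng.standard_normal(n)
        mirna_rows.append(row)
    mirna_values = (np.vstack(mirna_rows) if mirna_rows
                    else np.empty((0, n)))
    if len(mirna_ids):
        mirna_values = mirna_values + _baseline(
            rng, len(mirna_ids))[:, None]
    mirna_ds = ExpressionDataset(cohort_id, mirna_ids, samples,
                                 mirna_values, classes,
                                 {m: MIRNA for m in mirna_ids})
    truth = SimulationTruth(signal_pathway_id=signal_pathway_id,
                            signal_nodes=frozenset(signal_nodes),
                            effect_size=effect)
    return gene_ds, mirna_ds, truth


# -- full-study simulation -------------------------------------------------

def default_signal_pathway(pathway_id: str = "PW00",
                           ) -> tuple[PathwayGraph, set[str]]:
    """The canonical signal pathway: a 21-node chain of five 5-cliques
    with six affected genes confined to the two middle-left cliques."""
    pw = make_chain_pathway(pathway_id, n_cliques=5, clique_size=5)
    signal = {f"{pathway_id}_n{k:02d}" for k in (5, 6, 7, 9, 10, 11)}
    return pw, signal


def make_pathway_suite(n_decoys: int = 9,
                       ) -> tuple[list[PathwayGraph], str, set[str],
                                  dict[str, set[str]]]:
    """One signal pathway plus decoys, with per-pathway miRNA targets.

    Each pathway gets two candidate miRNAs targeting three of its genes,
    so augmentation has material to work with in every pathway.
    """
    signal_pw, signal_nodes = default_signal_pathway("PW00")
    pathways = [signal_pw] + [
        make_chain_pathway(f"PW{i + 1:02d}", n_cliques=5, clique_size=5)
        for i in range(n_decoys)]
    mirna_targets: dict[str, set[str]] = {}
    for pw in pathways:
        nodes = sorted(pw.gene_nodes())
        mirna_targets[f"mir-{pw.pathway_id}-a"] = set(nodes[4:7])
        mirna_targets[f"mir-{pw.pathway_id}-b"] = set(nodes[-4:-1])
    return pathways, "PW00", signal_nodes, mirna_targets


def _concat_datasets(ds1: ExpressionDataset, ds2: ExpressionDataset,
                     ) -> ExpressionDataset:
    if ds1.samples != ds2.samples or ds1.classes != ds2.classes:
        raise ValueError("datasets must share samples and classes")
    kinds = dict(ds1.feature_kinds)
    kinds.update(ds2.feature_kinds)
    return ExpressionDataset(
        ds1.cohort_id, ds1.features + ds2.features, ds1.samples,
        np.vstack([ds1.values, ds2.values]), ds1.classes, kinds)


def simulate_study(seed: int = 0, n_samples: tuple[int, int] = (96, 153),
                   positive_fraction: tuple[float, float] = (13 / 96,
                                                             22 / 153),
                   n_mirna: int = 300, n_gene: int = 2000,
                   plants: list[PlantedCircuit] | None = None,
                   n_decoy_pathways: int = 9, effect: float = 1.5,
                   cohort_ids: tuple[str, str] = ("cohortA", "cohortB")):
    """Simulate the full two-cohort study with shared planted truth.

    Both cohorts share the planted circuits, prior and pathway suite but
    have independent noise (two seeds derived from ``seed``), emulating
    the retrospective/prospective two-cohort design.  Returns
    ``(inputs_a, inputs_b, pathways, truth)`` where each inputs object is
    a :class:`mircuits.pipeline.CohortInputs`.
    """
    from .pipeline import CohortInputs

    rng = np.random.default_rng(seed)
    if plants is None:
        plants = default_plants(3, 3, strength_range=(0.6, 0.8), rng=rng)
    pathways, signal_id, signal_nodes, mirna_targets = \
        make_pathway_suite(n_decoy_pathways)

    inputs = []
    prior_union = InteractionPrior(set())
    for k, cohort_id in enumerate(cohort_ids):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        n = n_samples[k]
        n_pos = max(3, int(round(positive_fraction[k] * n)))
        mirna_c, gene_c, prior_c, truth_c = simulate_cohort(
            n_samples=n, n_mirna=max(0, n_mirna - len(mirna_targets)),
            n_gene=n_gene, circuits=plants,
            positive_fraction=n_pos / n, cohort_id=cohort_id,
            seed=sub_seed)
        gene_p, mirna_p, _truth_p = simulate_pathway_cohort(
            pathways, signal_id, signal_nodes, effect=effect,
            n_pos=n_pos, n_neg=n - n_pos, cohort_id=cohort_id,
            seed=sub_seed + 1, mirna_targets=mirna_targets)
        gene_ds = _concat_datasets(gene_c, gene_p)
        mirna_ds = _concat_datasets(mirna_c, mirna_p)
        prior_union = prior_union.union(prior_c)
        inputs.append((mirna_ds, gene_ds))
    for mirna, targets in mirna_targets.items():
        for t in sorted(targets):
            prior_union.add(PriorEdge(mirna, t, MIRNA_TARGET))

    truth = SimulationTruth(
        circuits=list(plants), signal_pathway_id=signal_id,
        signal_nodes=frozenset(signal_nodes), effect_size=effect)
    inputs_a = CohortInputs(inputs[0][0], inputs[0][1], prior_union)
    inputs_b = CohortInputs(inputs[1][0], inputs[1][1], prior_union)
    return inputs_a, inputs_b, pathways, truth


def evaluate_recovery(inferred, truth: SimulationTruth,
                      ) -> tuple[float, float]:
    """Precision and recall of inferred circuits against planted truth.

    Matching is on (topology, tf, mirna, gene).  Conventions: precision
    is 1 when nothing was inferred; recall is 1 when nothing was planted.
    """
    inferred_keys = {c.key if isinstance(c, MixedCircuit) else tuple(c)
                     for c in inferred}
    truth_keys = truth.circuit_keys()
    tp = len(inferred_keys & truth_keys)
    precision = 1.0 if not inferred_keys else tp / len(inferred_keys)
    recall = 1.0 if not truth_keys else tp / len(truth_keys)
    return precision, recall
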