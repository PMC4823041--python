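"""Topological pathway analysis on miRNA-augmented pathway graphs.

Each pathway graph is decomposed into a junction tree of cliques; every
clique is scored with a Gaussian log-likelihood-ratio statistic comparing
class-specific (mean, shrinkage-regularized covariance) fits against a
pooled fit.  The pathway statistic is the sum of clique statistics, and
its significance comes from class-label permutations.  Within significant
pathways, "portions" — simple clique paths through the junction tree —
are scored (mean clique statistic) and the top upper-percentile portions
are retained; their union forms a meta-pathway that is re-analysed the
same way.  Finally the per-cohort selections are merged into a union
network annotated with per-cohort log2ratios and filtered by the
cross-cohort discrepancy rule.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .cliquetree import JunctionTree, pathway_junction_tree
from .datasets import (ExpressionDataset, GENE, MIRNA, NodeAnnotation,
                       annotate_nodes)
from .networks import RegulatoryNetwork
from .pathways import PathwayGraph, augment_pathway
from .priors import InteractionPrior

logger = logging.getLogger(__name__)

_EPS = 1e-12


# -- clique statistic ------------------------------------------------------

def _lrt_batch(x: np.ndarray, z: np.ndarray, ridge: float) -> np.ndarray:
    """Gaussian LRT statistics for P class assignments at once.

    Parameters
    ----------
    x : ndarray, shape (k, n)
        Expression of the clique's k variables across n samples.
    z : ndarray of bool, shape (P, n)
        One positive-class mask per row; every row must split the samples
        into two non-empty groups.
    ridge : float
        Diagonal shrinkage, as a multiple of the mean pooled variance.

    Returns
    -------
    ndarray, shape (P,)
        ``n log|C0| - n1 log|C1| - n2 log|C2|`` per assignment, clipped at
        zero (regularization can push it marginally negative).
    """
    k, n = x.shape
    m0 = x.mean(axis=1)
    xc = x - m0[:, None]
    c0 = xc @ xc.T / n
    lam = max(ridge * float(np.mean(np.diag(c0))), _EPS)
    eye = lam * np.eye(k)

    n1 = z.sum(axis=1).astype(float)
    n2 = n - n1
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("each class assignment needs both classes")
    zf = z.astype(float)
    s1 = x @ zf.T                                   # (k, P)
    m1 = s1 / n1                                    # (k, P)
    q1 = np.einsum("kn,pn,ln->pkl", x, zf, x, optimize=True)
    c1 = q1 / n1[:, None, None] - m1.T[:, :, None] * m1.T[:, None, :]

    s2 = x.sum(axis=1)[:, None] - s1
    m2 = s2 / n2
    q2 = (x @ x.T)[None, :, :] - q1
    c2 = q2 / n2[:, None, None] - m2.T[:, :, None] * m2.T[:, None, :]

    _, ld0 = np.linalg.slogdet(c0 + eye)
    _, ld1 = np.linalg.slogdet(c1 + eye[None, :, :])
    _, ld2 = np.linalg.slogdet(c2 + eye[None, :, :])
    stat = n * ld0 - n1 * ld1 - n2 * ld2
    return np.clip(stat, 0.0, None)


def clique_statistic(x_pos: np.ndarray, x_neg: np.ndarray,
                     ridge: float = 1e-3) -> float:
    """Gaussian LRT for one clique given the two class submatrices.

    Rows are the clique variables; both submatrices need >= 3 samples.
    Zero when the two class distributions coincide; grows with the
    between-class difference in means and covariances.
    """
    x_pos = np.atleast_2d(np.asarray(x_pos, dtype=float))
    x_neg = np.atleast_2d(np.asarray(x_neg, dtype=float))
    if x_pos.shape[0] != x_neg.shape[0]:
        raise ValueError("class submatrices must share their variables")
    if x_pos.shape[1] < 3 or x_neg.shape[1] < 3:
        raise ValueError("need >= 3 samples per class")
    x = np.hstack([x_pos, x_neg])
    z = np.zeros((1, x.shape[1]), dtype=bool)
    z[0, :x_pos.shape[1]] = True
    return float(_lrt_batch(x, z, ridge)[0])


# -- per-pathway fit -------------------------------------------------------

@dataclass
class PortionScore:
    """A scored simple clique path through a pathway's junction tree.

    ``score`` is the permutation-standardized path statistic: the path's
    summed clique statistics, centred and scaled by the label-permutation
    null.  Standardization is what lets a path of several jointly
    modulated cliques outscore its best single clique, so top portions
    localize the modulated subnetwork rather than a single clique.
    ``mean_stat`` keeps the raw mean clique statistic for reference.
    """

    pathway_id: str
    clique_path: tuple[int, ...]
    nodes: frozenset[str]
    score: float
    p_value: float
    mean_stat: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("permutation p-value must lie in (0, 1]")


@dataclass
class PathwayFit:
    """Junction-tree decomposition plus observed and null clique scores."""

    pathway: PathwayGraph
    jtree: JunctionTree
    clique_nodes: list[tuple[str, ...]]     # expression-backed nodes only
    clique_stats: np.ndarray                # (n_cliques,)
    null_clique_stats: np.ndarray           # (n_perm, n_cliques)
    dropped_nodes: tuple[str, ...] = ()

    @property
    def statistic(self) -> float:
        return float(self.clique_stats.sum())

    @property
    def p_value(self) -> float:
        null = self.null_clique_stats.sum(axis=1)
        return float((1 + np.sum(null >= self.statistic))
                     / (1 + null.shape[0]))


def _expression_matrix(pathway: PathwayGraph, mirna_ds: ExpressionDataset,
                       gene_ds: ExpressionDataset,
                       ) -> tuple[dict[str, np.ndarray], tuple[str, ...]]:
    """Map each pathway node to its expression row; report the missing."""
    rows: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for node in pathway.nodes:
        source = mirna_ds if pathway.kind_of(node) == MIRNA else gene_ds
        other = gene_ds if source is mirna_ds else mirna_ds
        if node in source:
            rows[node] = source.row(node)
        elif node in other:
            rows[node] = other.row(node)
        else:
            dropped.append(node)
    if dropped:
        logger.info("pathway %s: %d nodes lack expression rows",
                    pathway.pathway_id, len(dropped))
    return rows, tuple(sorted(dropped))


def _permutation_masks(mask: np.ndarray, n_perm: int,
                       rng: np.random.Generator) -> np.ndarray:
    z = np.tile(mask, (n_perm, 1))
    return rng.permuted(z, axis=1)


def _rng_for(cfg: AnalysisConfig, tag: str) -> np.random.Generator:
    """Stable per-pathway stream: independent of pathway ordering."""
    return np.random.default_rng(
        [cfg.rng_seed & 0x7FFFFFFF, zlib.crc32(tag.encode())])


def fit_pathway(pathway: PathwayGraph, mirna_ds: ExpressionDataset,
                gene_ds: ExpressionDataset, cfg: AnalysisConfig,
                n_permutations: int | None = None) -> PathwayFit | None:
    """Decompose a pathway and score its cliques over label permutations.

    Returns None (with a warning) when fewer than two pathway nodes have
    expression rows.  Junction-tree structure comes from the full
    topology; nodes without expression are dropped from cliques before
    fitting.
    """
    if mirna_ds.samples != gene_ds.samples:
        raise ValueError("cohort matrices must share their sample list")
    if mirna_ds.classes != gene_ds.classes:
        raise ValueError("cohort matrices must share their class labels")
    gene_ds.require_min_class_size(3)
    n_perm = n_permutations or cfg.n_permutations

    rows, dropped = _expression_matrix(pathway, mirna_ds, gene_ds)
    if len(rows) < 2:
        logger.warning("pathway %s skipped: only %d nodes with expression",
                       pathway.pathway_id, len(rows))
        return None
    jtree = pathway_junction_tree(pathway.graph)
    mask = gene_ds.class_mask
    rng = _rng_for(cfg, pathway.pathway_id)
    z_null = _permutation_masks(mask, n_perm, rng)

    clique_nodes: list[tuple[str, ...]] = []
    stats = np.zeros(jtree.n_cliques)
    null = np.zeros((n_perm, jtree.n_cliques))
    for i, clique in enumerate(jtree.cliques):
        nodes = tuple(sorted(n for n in clique if n in rows))
        clique_nodes.append(nodes)
        if not nodes:
            continue
        x = np.vstack([rows[n] for n in nodes])
        stats[i] = _lrt_batch(x, mask[None, :], cfg.covariance_ridge)[0]
        null[:, i] = _lrt_batch(x, z_null, cfg.covariance_ridge)
    return PathwayFit(pathway, jtree, clique_nodes, stats, null,
                      dropped_nodes=dropped)


def pathway_significance(pathway: PathwayGraph,
                         mirna_ds: ExpressionDataset,
                         gene_ds: ExpressionDataset,
                         cfg: AnalysisConfig,
                         n_permutations: int | None = None,
                         ) -> float | None:
    """Whole-pathway permutation p-value, (1+exceed)/(1+n_perm)."""
    fit = fit_pathway(pathway, mirna_ds, gene_ds, cfg, n_permutations)
    return None if fit is None else fit.p_value


# -- portions --------------------------------------------------------------

def score_portions(fit: PathwayFit, cfg: AnalysisConfig,
                   percentile: float | None = None) -> list[PortionScore]:
    """Score every simple clique path and keep the upper percentile.

    The score of a path is the mean of its cliques' statistics; the
    permutation p-value re-uses the per-clique null scores.  Paths scoring
    at or above the ``1 - portion_percentile`` quantile of all path scores
    in the pathway are returned, best first.
    """
    pct = cfg.portion_percentile if percentile is None else percentile
    paths = list(fit.jtree.simple_paths(cfg.portion_length_cap))
    if not paths:
        return []
    scored = []
    for path in paths:
        idx = list(path)
        t_obs = float(fit.clique_stats[idx].sum())
        null = fit.null_clique_stats[:, idx].sum(axis=1)
        mu, sd = float(null.mean()), float(null.std())
        z = (t_obs - mu) / sd if sd > 0 else 0.0
        p = float((1 + np.sum(null >= t_obs)) / (1 + null.shape[0]))
        scored.append((path, z, p, t_obs / len(idx)))
    zs = np.array([s[1] for s in scored])
    cutoff = float(np.quantile(zs, 1.0 - pct))
    portions: list[PortionScore] = []
    for path, z, p, mean_stat in scored:
        if z < cutoff:
            continue
        nodes = frozenset().union(*(fit.clique_nodes[i] for i in path))
        portions.append(PortionScore(fit.pathway.pathway_id, tuple(path),
                                     frozenset(nodes), z, p, mean_stat))
    portions.sort(key=lambda s: (-s.score, s.clique_path))
    return portions


def build_meta_pathway(portions: list[PortionScore],
                       pathways: list[PathwayGraph],
                       meta_id: str = "meta") -> PathwayGraph:
    """Node-merged union of the portions' subnetworks.

    A portion's subnetwork is the induced subgraph of its (augmented)
    pathway on the portion's nodes; shared IDs merge into single nodes
    and edges keep a ``pathways`` provenance attribute.
    """
    by_id = {p.pathway_id: p for p in pathways}
    g = nx.DiGraph()
    for portion in portions:
        src = by_id[portion.pathway_id].graph
        sub = src.subgraph(portion.nodes)
        for n, d in sub.nodes(data=True):
            g.add_node(n, kind=d.get("kind", GENE))
        for u, v, d in sub.edges(data=True):
            if g.has_edge(u, v):
                prov = set(g.edges[u, v]["pathways"].split(","))
                prov.add(portion.pathway_id)
                g.edges[u, v]["pathways"] = ",".join(sorted(prov))
            else:
                g.add_edge(u, v,
                           interaction=d.get("interaction", "interacts"),
                           pathways=portion.pathway_id)
    return PathwayGraph(meta_id, "meta-pathway", g, augmented=True)


def select_meta_elements(meta: PathwayGraph, mirna_ds: ExpressionDataset,
                         gene_ds: ExpressionDataset, cfg: AnalysisConfig,
                         n_permutations: int | None = None) -> set[str]:
    """Re-analyse the meta-pathway; union of nodes in its top portions."""
    if meta.graph.number_of_nodes() == 0:
        return set()
    fit = fit_pathway(meta, mirna_ds, gene_ds, cfg, n_permutations)
    if fit is None:
        return set()
    selected: set[str] = set()
    for portion in score_portions(fit, cfg):
        selected |= portion.nodes
    return selected


# -- cross-cohort union network -------------------------------------------

def union_network(sel_a: set[str], sel_b: set[str],
                  meta_a: PathwayGraph, meta_b: PathwayGraph,
                  ann_a: dict[str, NodeAnnotation],
                  ann_b: dict[str, NodeAnnotation],
                  cfg: AnalysisConfig) -> RegulatoryNetwork:
    """Merge per-cohort meta-pathway selections into one annotated network.

    For every candidate node the cross-cohort log2ratio discrepancy
    ``d = |lr_A - lr_B|`` is evaluated: sign-discordant nodes with
    ``d > discrepancy_max`` are discarded ('difference' mode discards on
    the distance alone); surviving discordant nodes are displayed neutral
    and concordant nodes are coloured by the reference cohort's
    log2ratio.  Edges are the union of meta-pathway edges among surviving
    nodes.
    """
    cohort_a = next(iter(ann_a.values())).cohort_id if ann_a else None
    ref_is_a = (cfg.reference_cohort is None
                or cfg.reference_cohort == cohort_a)
    candidates = sorted(sel_a | sel_b)
    net = RegulatoryNetwork()
    kept: set[str] = set()
    for node in candidates:
        a, b = ann_a.get(node), ann_b.get(node)
        if a is None or b is None:
            logger.info("union network: %s dropped (missing annotation "
                        "in one cohort)", node)
            continue
        d = abs(a.log2ratio - b.log2ratio)
        concordant = a.log2ratio * b.log2ratio >= 0
        discard = (d > cfg.discrepancy_max
                   if cfg.discrepancy_mode == "difference"
                   else (not concordant and d > cfg.discrepancy_max))
        if discard:
            continue
        state = "colored" if concordant else "neutral"
        ref = a if ref_is_a else b
        net.add_node(node, kind=a.kind, display_state=state,
                     log2ratio=ref.log2ratio if state == "colored" else 0.0,
                     log2ratio_A=a.log2ratio, log2ratio_B=b.log2ratio)
        kept.add(node)
    for meta in (meta_a, meta_b):
        for u, v, d_attr in meta.graph.edges(data=True):
            if u in kept and v in kept:
                if not net.graph.has_edge(u, v):
                    net.graph.add_edge(
                        u, v, sign=-1 if d_attr.get("interaction")
                        == "represses" else 1, weight=1.0,
                        interaction=d_attr.get("interaction", "interacts"))
    return net


# -- model / results facade ------------------------------------------------

@dataclass
class PathwayTopologyResults:
    """Per-cohort output of :class:`PathwayTopologyModel`.

    Attributes
    ----------
    table : DataFrame
        One row per analysable pathway: statistic, p-value, significance.
    fits : dict
        Pathway ID -> :class:`PathwayFit` (None where skipped).
    portions : list of PortionScore
        Top portions of every significant pathway.
    meta : PathwayGraph
        Meta-pathway assembled from the portions.
    selected_nodes : set of str
        Nodes of the meta-pathway's own top portions.
    annotations : dict
        Node -> :class:`NodeAnnotation` (log2ratio in this cohort).
    """

    cohort_id: str
    table: pd.DataFrame
    fits: dict[str, PathwayFit | None]
    portions: list[PortionScore]
    meta: PathwayGraph
    selected_nodes: set[str]
    annotations: dict[str, NodeAnnotation] = field(default_factory=dict)

    @property
    def significant_pathways(self) -> list[str]:
        t = self.table
        return t.loc[t["significant"], "pathway_id"].tolist()

    def summary(self) -> pd.DataFrame:
        """Pathways ranked by p-value, ties broken by the observed
        statistic (larger first), then ID for determinism."""
        return self.table.sort_values(
            ["p_value", "statistic", "pathway_id"],
            ascending=[True, False, True],
            kind="stable").reset_index(drop=True)


class PathwayTopologyModel:
    """Topological pathway analysis of one cohort.

    Parameters
    ----------
    pathways : list of PathwayGraph
        Raw (non-augmented) pathway topologies.
    mirna_ds, gene_ds : ExpressionDataset
        Paired matrices over an identical sample list with shared class
        labels.
    prior : InteractionPrior
        Supplies the miRNA target edges used for pathway augmentation.
    config : AnalysisConfig
    """

    def __init__(self, pathways: list[PathwayGraph],
                 mirna_ds: ExpressionDataset, gene_ds: ExpressionDataset,
                 prior: InteractionPrior,
                 config: AnalysisConfig | None = None) -> None:
        self.pathways = list(pathways)
        self.mirna_ds = mirna_ds
        self.gene_ds = gene_ds
        self.prior = prior
        self.config = config or AnalysisConfig()

    def fit(self, n_permutations: int | None = None,
            pooled_portions: bool = False) -> PathwayTopologyResults:
        cfg = self.config
        expressed = set(self.mirna_ds.features)
        augmented = [augment_pathway(p, self.prior, expressed)
                     for p in self.pathways]
        fits: dict[str, PathwayFit | None] = {}
        rows = []
        for p in augmented:
            fit = fit_pathway(p, self.mirna_ds, self.gene_ds, cfg,
                              n_permutations)
            fits[p.pathway_id] = fit
            if fit is None:
                continue
            rows.append({
                "pathway_id": p.pathway_id, "name": p.name,
                "n_nodes": p.graph.number_of_nodes(),
                "n_mirnas": len(p.mirna_nodes()),
                "n_cliques": fit.jtree.n_cliques,
                "statistic": fit.statistic, "p_value": fit.p_value,
            })
        table = pd.DataFrame(rows, columns=["pathway_id", "name",
                                            "n_nodes", "n_mirnas",
                                            "n_cliques", "statistic",
                                            "p_value"])
        table["significant"] = table["p_value"] < cfg.pathway_alpha

        sig_fits = [fits[pid] for pid in table.loc[table["significant"],
                                                   "pathway_id"]]
        portions: list[PortionScore] = []
        if pooled_portions and sig_fits:
            # pool standardized path scores across significant pathways
            # before applying the percentile cutoff
            per_fit = [score_portions(f, cfg, percentile=1.0)
                       for f in sig_fits]
            all_scores = np.array([s.score for lst in per_fit
                                   for s in lst])
            if all_scores.size:
                cutoff = float(np.quantile(all_scores,
                                           1.0 - cfg.portion_percentile))
                for lst in per_fit:
                    portions.extend(s for s in lst if s.score >= cutoff)
        else:
            for f in sig_fits:
                portions.extend(score_portions(f, cfg))

        meta = build_meta_pathway(
            portions, augmented, meta_id=f"meta_{self.gene_ds.cohort_id}")
        selected = select_meta_elements(meta, self.mirna_ds, self.gene_ds,
                                        cfg, n_permutations)
        ann = annotate_nodes(self.gene_ds, meta.gene_nodes())
        ann.update(annotate_nodes(self.mirna_ds, meta.mirna_nodes()))
        return PathwayTopologyResults(
            cohort_id=self.gene_ds.cohort_id, table=table, fits=fits,
            portions=portions, meta=meta, selected_nodes=selected,
            annotations=ann)
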