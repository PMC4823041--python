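"""Mixed miRNA/TF/gene circuit inference from paired expression profiles.

Given one cohort's paired miRNA and gene expression matrices plus an
interaction prior, Pearson correlations are computed for every prior edge
and two feed-forward-loop topologies are enumerated:

* ``TF_activates_both`` — a TF positively correlated with both a miRNA and
  one of that miRNA's predicted target genes;
* ``miRNA_inhibits_both`` — a miRNA negatively correlated with both a TF
  and one of that TF's regulated genes.

The two edges anchored at the apex regulator must pass the correlation
threshold with the topology's sign; the third, closing edge of the
triangle is required only in the prior (its correlation is recorded but
not constrained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .datasets import ExpressionDataset, GENE, MIRNA, TF
from .networks import RegulatoryNetwork
from .priors import (InteractionPrior, MIRNA_TARGET, TF_GENE, TF_MIRNA)

logger = logging.getLogger(__name__)

TF_ACTIVATES_BOTH = "TF_activates_both"
MIRNA_INHIBITS_BOTH = "miRNA_inhibits_both"
TOPOLOGIES = (TF_ACTIVATES_BOTH, MIRNA_INHIBITS_BOTH)


@dataclass(frozen=True)
class CorrelationEdge:
    """Pearson correlation measured along one prior edge."""

    regulator: str
    target: str
    relation: str
    r: float
    n: int
    p: float = float("nan")

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of range: {self.r}")
        if self.n < 3:
            raise ValueError("correlation requires n >= 3 samples")


@dataclass(frozen=True)
class MixedCircuit:
    """One inferred miRNA/TF/gene triplet.

    ``r_tf_mirna``, ``r_tf_gene`` and ``r_mirna_gene`` carry the pairwise
    correlations; the closing edge of the triangle (miRNA-gene for the
    TF-apex topology, TF-gene for the miRNA-apex one) is unconstrained and
    may be NaN if its profile pair was degenerate.
    """

    topology: str
    tf: str
    mirna: str
    gene: str
    r_tf_mirna: float
    r_tf_gene: float
    r_mirna_gene: float
    cohort_id: str = ""

    @property
    def key(self) -> tuple[str, str, str, str]:
        """Identity used for cross-cohort intersection."""
        return (self.topology, self.tf, self.mirna, self.gene)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    # two-sided t-distribution p-value; reported, never used for filtering
    if abs(r) >= 1.0:
        return max(-1.0, min(1.0, r)), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), df=n - 2))


def prior_correlations(mirna_ds: ExpressionDataset,
                       gene_ds: ExpressionDataset,
                       prior: InteractionPrior) -> set[CorrelationEdge]:
    """Pearson correlation for every prior edge resolvable in the data.

    The two datasets must share an identical ordered sample list.  Edges
    whose endpoints are missing from the matrices, or whose profiles have
    zero variance, are skipped with a logged count.
    """
    if mirna_ds.samples != gene_ds.samples:
        raise ValueError("miRNA and gene datasets must share an identical "
                         "ordered sample list")
    if mirna_ds.n_samples < 3:
        raise ValueError("need >= 3 samples for correlation")

    def resolve(feature: str) -> np.ndarray | None:
        if feature in mirna_ds:
            return mirna_ds.row(feature)
        if feature in gene_ds:
            return gene_ds.row(feature)
        return None

    edges: set[CorrelationEdge] = set()
    n_unresolved = n_degenerate = 0
    for e in prior:
        x = resolve(e.regulator)
        y = resolve(e.target)
        if x is None or y is None:
            n_unresolved += 1
            continue
        if x.std() == 0.0 or y.std() == 0.0:
            n_degenerate += 1
            continue
        r, p = _pearson(x, y)
        edges.add(CorrelationEdge(e.regulator, e.target, e.relation,
                                  r=r, n=x.size, p=p))
    if n_unresolved:
        logger.info("%d prior edges unresolvable in expression data",
                    n_unresolved)
    if n_degenerate:
        logger.info("%d prior edges skipped for zero-variance profiles",
                    n_degenerate)
    return edges


def binary_relations(edges: set[CorrelationEdge], threshold: float,
                     allow_positive: bool = False) -> set[CorrelationEdge]:
    """Binary miRNA/target relations: anticorrelated repression.

    Keeps miRNA_target edges with ``r <= -threshold``; with
    ``allow_positive`` also those with ``r >= +threshold``.
    """
    out = set()
    for e in edges:
        if e.relation != MIRNA_TARGET:
            continue
        if e.r <= -threshold or (allow_positive and e.r >= threshold):
            out.add(e)
    return out


def find_mixed_circuits(mirna_ds: ExpressionDataset,
                        gene_ds: ExpressionDataset,
                        prior: InteractionPrior,
                        cfg: AnalysisConfig | None = None,
                        ) -> list[MixedCircuit]:
    """Enumerate mixed circuits passing the correlation threshold.

    Returns circuits sorted lexicographically by (topology, tf, mirna,
    gene); output is a deterministic function of the inputs.
    """
    cfg = cfg or AnalysisConfig()
    t = cfg.circuit_corr_threshold
    corr = prior_correlations(mirna_ds, gene_ds, prior)
    r_of = {(e.regulator, e.target): e.r for e in corr}

    tf_gene_targets: dict[str, set[str]] = {}
    for tf, g in prior.pairs(TF_GENE):
        tf_gene_targets.setdefault(tf, set()).add(g)
    mirna_targets: dict[str, set[str]] = {}
    for m, g in prior.pairs(MIRNA_TARGET):
        mirna_targets.setdefault(m, set()).add(g)

    circuits: list[MixedCircuit] = []

    # topology (i): TF -> miRNA and TF -> gene activations, with the
    # miRNA -> gene targeting as the prior-only closing edge
    for tf, mirna in sorted(prior.pairs(TF_MIRNA)):
        genes = tf_gene_targets.get(tf, set()) & mirna_targets.get(mirna,
                                                                   set())
        r_tm = r_of.get((tf, mirna))
        if r_tm is None or r_tm < t:
            continue
        for gene in sorted(genes - {tf, mirna}):
            r_tg = r_of.get((tf, gene))
            if r_tg is None or r_tg < t:
                continue
            r_mg = r_of.get((mirna, gene), float("nan"))
            circuits.append(MixedCircuit(
                TF_ACTIVATES_BOTH, tf, mirna, gene,
                r_tf_mirna=r_tm, r_tf_gene=r_tg, r_mirna_gene=r_mg,
                cohort_id=gene_ds.cohort_id))

    # topology (ii): the miRNA targets both the TF and the gene
    # (anticorrelated), with the TF -> gene regulation as the prior-only
    # closing edge
    for mirna, targets in sorted(mirna_targets.items()):
        for tf in sorted(targets):
            if tf not in tf_gene_targets:
                continue
            r_mt = r_of.get((mirna, tf))
            if r_mt is None or r_mt > -t:
                continue
            genes = tf_gene_targets[tf] & targets
            for gene in sorted(genes - {tf, mirna}):
                r_mg = r_of.get((mirna, gene))
                if r_mg is None or r_mg > -t:
                    continue
                r_tg = r_of.get((tf, gene), float("nan"))
                circuits.append(MixedCircuit(
                    MIRNA_INHIBITS_BOTH, tf, mirna, gene,
                    r_tf_mirna=r_mt, r_tf_gene=r_tg, r_mirna_gene=r_mg,
                    cohort_id=gene_ds.cohort_id))
    circuits.sort(key=lambda c: c.key)
    return circuits


def circuits_to_network(circuits, cfg: AnalysisConfig | None = None,
                        provenance: str | None = None) -> RegulatoryNetwork:
    """Project circuits onto a typed signed network.

    Nodes are tagged miRNA/TF/gene; each constrained circuit edge becomes
    a directed edge weighted by its correlation (duplicates keep the
    largest |r|).  The unconstrained closing edge is included when its
    correlation is known, signed by that correlation.
    """
    net = RegulatoryNetwork()
    for c in circuits:
        net.add_node(c.tf, kind=TF)
        net.add_node(c.mirna, kind=MIRNA)
        net.add_node(c.gene, kind=GENE)
        attrs = {} if provenance is None else {"provenance": provenance}
        if c.topology == TF_ACTIVATES_BOTH:
            net.add_edge(c.tf, c.mirna, sign=1, weight=c.r_tf_mirna, **attrs)
            net.add_edge(c.tf, c.gene, sign=1, weight=c.r_tf_gene, **attrs)
            if np.isfinite(c.r_mirna_gene):
                net.add_edge(c.mirna, c.gene,
                             sign=1 if c.r_mirna_gene >= 0 else -1,
                             weight=c.r_mirna_gene, **attrs)
        else:
            net.add_edge(c.mirna, c.tf, sign=-1, weight=c.r_tf_mirna, **attrs)
            net.add_edge(c.mirna, c.gene, sign=-1, weight=c.r_mirna_gene,
                         **attrs)
            if np.isfinite(c.r_tf_gene):
                net.add_edge(c.tf, c.gene,
                             sign=1 if c.r_tf_gene >= 0 else -1,
                             weight=c.r_tf_gene, **attrs)
    return net


def circuits_to_frame(circuits) -> pd.DataFrame:
    """Tabular circuit export (the unconstrained edge is left blank)."""
    rows = []
    for c in circuits:
        rows.append({
            "topology": c.topology, "tf": c.tf, "mirna": c.mirna,
            "gene": c.gene,
            "r_tf_mirna": c.r_tf_mirna,
            "r_tf_gene": (c.r_tf_gene if c.topology == TF_ACTIVATES_BOTH
                          else np.nan),
            "r_mirna_gene": (c.r_mirna_gene
                             if c.topology == MIRNA_INHIBITS_BOTH
                             else np.nan),
            "cohort": c.cohort_id,
        })
    return pd.DataFrame(rows, columns=["topology", "tf", "mirna", "gene",
                                       "r_tf_mirna", "r_tf_gene",
                                       "r_mirna_gene", "cohort"])
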