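"""Model/Results facade for per-cohort mixed-circuit inference."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .circuits import (CorrelationEdge, MixedCircuit, binary_relations,
                       circuits_to_frame, circuits_to_network,
                       find_mixed_circuits, prior_correlations)
from .config import AnalysisConfig
from .datasets import ExpressionDataset, filter_by_cv
from .networks import RegulatoryNetwork
from .priors import InteractionPrior


@dataclass
class MixedCircuitResults:
    """Fitted output of :class:`MixedCircuitModel`.

    Attributes
    ----------
    circuits : list of MixedCircuit
        Mixed miRNA/TF/gene circuits passing the correlation thresholds,
        in deterministic (topology, tf, mirna, gene) order.
    binary : set of CorrelationEdge
        Binary miRNA/target relations (anticorrelated at the binary
        threshold).
    correlations : set of CorrelationEdge
        Pearson correlations along every resolvable prior edge.
    network : RegulatoryNetwork
        Signed, typed projection of the circuits.
    """

    cohort_id: str
    config: AnalysisConfig
    circuits: list[MixedCircuit]
    binary: set[CorrelationEdge]
    correlations: set[CorrelationEdge]
    network: RegulatoryNetwork
    n_features_kept: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return circuits_to_frame(self.circuits)

    def summary(self) -> pd.DataFrame:
        """Per-stage counts, one row per quantity."""
        n_tf_apex = sum(c.topology == "TF_activates_both"
                        for c in self.circuits)
        rows = [
            ("cohort", self.cohort_id),
            ("genes kept by CV filter",
             self.n_features_kept.get("gene", "n/a")),
            ("miRNAs kept by CV filter",
             self.n_features_kept.get("miRNA", "n/a")),
            ("prior edges with correlations", len(self.correlations)),
            ("binary miRNA/target relations", len(self.binary)),
            ("mixed circuits", len(self.circuits)),
            ("  TF-apex circuits", n_tf_apex),
            ("  miRNA-apex circuits", len(self.circuits) - n_tf_apex),
            ("network nodes", self.network.n_nodes()),
            ("network edges", self.network.n_edges()),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])


class MixedCircuitModel:
    """Per-cohort inference of mixed miRNA/TF/gene circuits.

    Applies the coefficient-of-variation filter, computes Pearson
    correlations along prior edges, extracts binary miRNA/target
    relations and enumerates the two feed-forward circuit topologies.

    Parameters
    ----------
    mirna_ds, gene_ds : ExpressionDataset
        Paired log2 matrices over an identical ordered sample list.
    prior : InteractionPrior
    config : AnalysisConfig, optional
    """

    def __init__(self, mirna_ds: ExpressionDataset,
                 gene_ds: ExpressionDataset, prior: InteractionPrior,
                 config: AnalysisConfig | None = None) -> None:
        if mirna_ds.samples != gene_ds.samples:
            raise ValueError("miRNA and gene matrices must share an "
                             "identical ordered sample list")
        self.mirna_ds = mirna_ds
        self.gene_ds = gene_ds
        self.prior = prior
        self.config = config or AnalysisConfig()

    def fit(self) -> MixedCircuitResults:
        cfg = self.config
        genes = filter_by_cv(self.gene_ds, cfg.cv_keep_fraction)
        mirnas = (filter_by_cv(self.mirna_ds, cfg.cv_keep_fraction)
                  if cfg.cv_filter_mirnas else self.mirna_ds)
        correlations = prior_correlations(mirnas, genes, self.prior)
        binary = binary_relations(correlations,
                                  cfg.binary_corr_threshold,
                                  allow_positive=cfg.binary_allow_positive)
        circuits = find_mixed_circuits(mirnas, genes, self.prior, cfg)
        network = circuits_to_network(circuits, cfg)
        return MixedCircuitResults(
            cohort_id=self.gene_ds.cohort_id, config=cfg,
            circuits=circuits, binary=binary, correlations=correlations,
            network=network,
            n_features_kept={"gene": genes.n_features,
                             "miRNA": mirnas.n_features})
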