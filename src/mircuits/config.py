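"""Analysis configuration shared by every pipeline stage.

The defaults reproduce the published operating point of the workflow:
keep the 75% most variable genes, |r| >= 0.2 inside mixed circuits,
r <= -0.4 for binary miRNA/target repression, pathway significance at
P < 0.1 with 10,000 label permutations, and upper 10th-percentile
portion selection.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import yaml


@dataclass
class AnalysisConfig:
    """Tunable parameters of the circuit/pathway analysis.

    Parameters
    ----------
    cv_keep_fraction : float
        Fraction of features retained by the coefficient-of-variation
        filter, in (0, 1].
    cv_filter_mirnas : bool
        Whether the CV filter is also applied to the miRNA matrix.  The
        published procedure filters genes only.
    circuit_corr_threshold : float
        Minimum |Pearson r| for the two constrained edges of a mixed
        circuit.
    binary_corr_threshold : float
        Threshold for binary miRNA/target relations (anticorrelation,
        ``r <= -threshold``).
    binary_allow_positive : bool
        If True, binary relations with ``r >= +threshold`` are also kept.
        Off by default: miRNA-mediated repression is the modelled
        mechanism.
    pathway_alpha : float
        Significance cutoff for whole-pathway permutation p-values.
    n_permutations : int
        Number of class-label permutations for pathway/portion scoring.
    portion_percentile : float
        Upper quantile of clique-path scores retained as "portions".
    portion_length_cap : int
        Maximum number of cliques in a scored junction-tree path.
    covariance_ridge : float
        Shrinkage added to clique covariance diagonals, as a multiple of
        the mean pooled diagonal.
    discrepancy_max : float
        Maximum tolerated cross-cohort log2ratio discrepancy (log2 units)
        for sign-discordant union-network nodes.
    discrepancy_mode : str
        'sign' (default): discard only sign-discordant nodes whose
        log2ratio difference exceeds ``discrepancy_max``; 'difference':
        discard any node whose difference exceeds it regardless of sign.
    reference_cohort : str | None
        Cohort whose measurements win when both cohorts supply a node or
        edge attribute.
    rng_seed : int
        Seed for every stochastic stage (permutations, simulation).
    """

    cv_keep_fraction: float = 0.75
    cv_filter_mirnas: bool = False
    circuit_corr_threshold: float = 0.2
    binary_corr_threshold: float = 0.4
    binary_allow_positive: bool = False
    pathway_alpha: float = 0.1
    n_permutations: int = 10_000
    portion_percentile: float = 0.10
    portion_length_cap: int = 10
    covariance_ridge: float = 1e-3
    discrepancy_max: float = 0.1
    discrepancy_mode: str = "sign"
    reference_cohort: str | None = None
    rng_seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.cv_keep_fraction <= 1.0:
            raise ValueError("cv_keep_fraction must be in (0, 1]")
        for name in ("circuit_corr_threshold", "binary_corr_threshold",
                     "discrepancy_max", "covariance_ridge"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.portion_percentile <= 1.0:
            raise ValueError("portion_percentile must be in (0, 1]")
        if not 0.0 < self.pathway_alpha < 1.0:
            raise ValueError("pathway_alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if self.discrepancy_mode not in ("sign", "difference"):
            raise ValueError("discrepancy_mode must be 'sign' or 'difference'")
        if self.circuit_corr_threshold > self.binary_corr_threshold:
            warnings.warn(
                "circuit_corr_threshold exceeds binary_corr_threshold; "
                "binary relations will be stricter than circuit edges",
                stacklevel=2,
            )

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
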