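"""Interaction priors: typed regulator -> target edge sets.

Three relation kinds are understood: ``miRNA_target`` (miRNA represses a
gene), ``TF_gene`` (TF regulates a gene) and ``TF_miRNA`` (TF drives a
miRNA).  Predictions (e.g. TargetScan output) and validated interactions
are both consumed as edge-list TSV files with columns
``regulator  target  relation  evidence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

MIRNA_TARGET = "miRNA_target"
TF_GENE = "TF_gene"
TF_MIRNA = "TF_miRNA"
RELATION_KINDS = (MIRNA_TARGET, TF_GENE, TF_MIRNA)

PREDICTED = "predicted"
VALIDATED = "validated"
EVIDENCE_TAGS = (PREDICTED, VALIDATED)


@dataclass(frozen=True)
class PriorEdge:
    regulator: str
    target: str
    relation: str
    evidence: str = PREDICTED

    def __post_init__(self) -> None:
        if self.regulator == self.target:
            raise ValueError(f"self-edge not allowed: {self.regulator!r}")
        if self.relation not in RELATION_KINDS:
            raise ValueError(f"unknown relation kind {self.relation!r}")
        if self.evidence not in EVIDENCE_TAGS:
            raise ValueError(f"unknown evidence tag {self.evidence!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.regulator, self.target)


@dataclass
class InteractionPrior:
    """Deduplicated set of typed regulator -> target edges."""

    edges: set[PriorEdge] = field(default_factory=set)

    def __post_init__(self) -> None:
        # deduplicate on (regulator, target, relation); validated wins
        by_key: dict[tuple[str, str, str], PriorEdge] = {}
        for e in self.edges:
            key = (e.regulator, e.target, e.relation)
            old = by_key.get(key)
            if old is None or (old.evidence == PREDICTED
                               and e.evidence == VALIDATED):
                by_key[key] = e
        self.edges = set(by_key.values())

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def of_kind(self, relation: str) -> set[PriorEdge]:
        return {e for e in self.edges if e.relation == relation}

    def pairs(self, relation: str) -> set[tuple[str, str]]:
        return {e.pair for e in self.edges if e.relation == relation}

    def targets_of(self, regulator: str, relation: str) -> set[str]:
        return {e.target for e in self.edges
                if e.relation == relation and e.regulator == regulator}

    def regulators(self, relation_prefix: str = "TF_") -> set[str]:
        """IDs acting as regulators of the given relation family.

        Features count as TF-capable only if they appear as regulators of
        a ``TF_*`` relation in the prior.
        """
        return {e.regulator for e in self.edges
                if e.relation.startswith(relation_prefix)}

    def add(self, edge: PriorEdge) -> None:
        self.edges.add(edge)

    def union(self, other: "InteractionPrior") -> "InteractionPrior":
        return InteractionPrior(self.edges | other.edges)


def load_prior(path) -> InteractionPrior:
    """Read an edge-list TSV with columns regulator/target/relation/evidence."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"regulator", "target", "relation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"prior file {path} lacks columns {sorted(missing)}")
    if "evidence" not in df.columns:
        df["evidence"] = PREDICTED
    edges = {
        PriorEdge(r.regulator, r.target, r.relation, r.evidence)
        for r in df.itertuples(index=False)
    }
    return InteractionPrior(edges)


def write_prior(prior: InteractionPrior, path) -> None:
    rows = sorted(
        (e.regulator, e.target, e.relation, e.evidence) for e in prior
    )
    pd.DataFrame(rows, columns=["regulator", "target", "relation",
                                "evidence"]).to_csv(path, sep="\t",
                                                    index=False)


def build_prior(edges: Iterable[tuple[str, str, str]],
                evidence: str = PREDICTED) -> InteractionPrior:
    """Convenience constructor from (regulator, target, relation) triples."""
    return InteractionPrior({PriorEdge(r, t, k, evidence)
                             for r, t, k in edges})
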