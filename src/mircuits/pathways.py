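"""Pathway topologies and their miRNA augmentation.

Pathways arrive as typed node/edge lists (e.g. KEGG-derived topologies
exported to text).  Augmentation follows the published rule: a miRNA is
added to a pathway-derived network only if at least one of its validated
or predicted target genes is already a pathway component, and then with a
directed repression edge to each such target; the gene-gene topology is
never altered.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .datasets import GENE, MIRNA
from .priors import InteractionPrior, MIRNA_TARGET

logger = logging.getLogger(__name__)


class PathwayGraph:
    """A typed directed biological network, optionally miRNA-augmented."""

    def __init__(self, pathway_id: str, name: str | None = None,
                 graph: nx.DiGraph | None = None,
                 augmented: bool = False) -> None:
        self.pathway_id = pathway_id
        self.name = name or pathway_id
        self.graph = graph if graph is not None else nx.DiGraph()
        self.augmented = augmented

    def add_gene(self, node: str) -> None:
        self.graph.add_node(node, kind=GENE)

    def add_edge(self, source: str, target: str,
                 interaction: str = "interacts", kind_source: str = GENE,
                 kind_target: str = GENE) -> None:
        if source not in self.graph:
            self.graph.add_node(source, kind=kind_source)
        if target not in self.graph:
            self.graph.add_node(target, kind=kind_target)
        self.graph.add_edge(source, target, interaction=interaction)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def kind_of(self, node: str) -> str:
        return self.graph.nodes[node].get("kind", GENE)

    def gene_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True)
                if d.get("kind", GENE) != MIRNA}

    def mirna_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True)
                if d.get("kind") == MIRNA}

    def copy(self, pathway_id: str | None = None) -> "PathwayGraph":
        return PathwayGraph(pathway_id or self.pathway_id, self.name,
                            self.graph.copy(), self.augmented)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"PathwayGraph({self.pathway_id!r}, "
                f"{self.graph.number_of_nodes()} nodes, "
                f"{self.graph.number_of_edges()} edges, "
                f"augmented={self.augmented})")


def augment_pathway(pathway: PathwayGraph, prior: InteractionPrior,
                    expressed_mirnas: set[str]) -> PathwayGraph:
    """Add expressed miRNAs whose prior targets intersect the pathway.

    Each qualifying miRNA is added once, with one directed ``represses``
    edge to every one of its targets already present as a pathway gene.
    Gene-gene edges are untouched.
    """
    out = pathway.copy()
    genes = pathway.gene_nodes()
    added = 0
    for mirna in sorted(expressed_mirnas):
        hits = prior.targets_of(mirna, MIRNA_TARGET) & genes
        if not hits:
            continue
        out.graph.add_node(mirna, kind=MIRNA)
        for g in sorted(hits):
            out.graph.add_edge(mirna, g, interaction="represses")
        added += 1
    out.augmented = True
    if added:
        logger.info("pathway %s: %d miRNAs added", pathway.pathway_id,
                    added)
    return out


# -- IO --------------------------------------------------------------------

def write_pathway(pathway: PathwayGraph, directory) -> None:
    """Write ``<id>.nodes.tsv`` and ``<id>.edges.tsv`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        [(n, d.get("kind", GENE)) for n, d in
         sorted(pathway.graph.nodes(data=True))],
        columns=["id", "kind"])
    nodes.to_csv(directory / f"{pathway.pathway_id}.nodes.tsv", sep="\t",
                 index=False)
    edges = pd.DataFrame(
        [(u, v, d.get("interaction", "interacts")) for u, v, d in
         sorted(pathway.graph.edges(data=True))],
        columns=["source", "target", "interaction"])
    edges.to_csv(directory / f"{pathway.pathway_id}.edges.tsv", sep="\t",
                 index=False)


def load_pathway(directory, pathway_id: str, name: str | None = None,
                 ) -> PathwayGraph:
    directory = Path(directory)
    nodes = pd.read_csv(directory / f"{pathway_id}.nodes.tsv", sep="\t",
                        dtype=str)
    edges = pd.read_csv(directory / f"{pathway_id}.edges.tsv", sep="\t",
                        dtype=str)
    g = nx.DiGraph()
    for row in nodes.itertuples(index=False):
        g.add_node(row.id, kind=row.kind)
    for row in edges.itertuples(index=False):
        for endpoint in (row.source, row.target):
            if endpoint not in g:
                raise ValueError(
                    f"pathway {pathway_id}: edge endpoint {endpoint!r} "
                    "missing from node list")
        g.add_edge(row.source, row.target, interaction=row.interaction)
    return PathwayGraph(pathway_id, name, g)


def write_pathway_collection(pathways: list[PathwayGraph], directory,
                             ) -> None:
    """Directory-of-pathways layout with an ``index.tsv`` file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for p in pathways:
        write_pathway(p, directory)
    index = pd.DataFrame([(p.pathway_id, p.name) for p in pathways],
                         columns=["pathway_id", "name"])
    index.to_csv(directory / "index.tsv", sep="\t", index=False)


def load_pathway_collection(directory) -> list[PathwayGraph]:
    directory = Path(directory)
    index = pd.read_csv(directory / "index.tsv", sep="\t", dtype=str)
    return [load_pathway(directory, row.pathway_id, row.name)
            for row in index.itertuples(index=False)]
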