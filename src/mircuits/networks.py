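"""Regulatory networks: typed signed digraphs with GraphML/SIF export."""

from __future__ import annotations

import networkx as nx

PROV_A = "A"
PROV_B = "B"
PROV_BOTH = "both"


class RegulatoryNetwork:
    """Typed, signed, weighted directed network of regulatory relations.

    Thin wrapper over :class:`networkx.DiGraph`.  Node attributes: ``kind``
    (miRNA | TF | gene) and optional ``seed`` flag; edge attributes:
    ``sign`` (+1/-1), ``weight`` (Pearson r of the supporting relation)
    and ``provenance`` (cohort of origin: 'A', 'B' or 'both').
    """

    def __init__(self, graph: nx.DiGraph | None = None) -> None:
        self.graph = graph if graph is not None else nx.DiGraph()

    # -- construction ------------------------------------------------------

    def add_node(self, node: str, kind: str, **attrs) -> None:
        self.graph.add_node(node, kind=kind, **attrs)

    def add_edge(self, source: str, target: str, sign: int, weight: float,
                 **attrs) -> None:
        """Add an edge, deduplicating by keeping the largest |weight|."""
        if self.graph.has_edge(source, target):
            old = self.graph.edges[source, target]
            if abs(old["weight"]) >= abs(weight):
                return
        self.graph.add_edge(source, target, sign=int(sign),
                            weight=float(weight), **attrs)

    # -- views -------------------------------------------------------------

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def signed_pairs(self) -> set[tuple[str, str, int]]:
        """Relationship identity used for cross-cohort sharing."""
        return {(u, v, d["sign"]) for u, v, d in self.graph.edges(data=True)}

    def neighbors(self, node: str) -> set[str]:
        """Undirected first neighbours (predecessors and successors)."""
        return set(self.graph.successors(node)) | set(
            self.graph.predecessors(node))

    def induced(self, nodes) -> "RegulatoryNetwork":
        return RegulatoryNetwork(self.graph.subgraph(nodes).copy())

    def copy(self) -> "RegulatoryNetwork":
        return RegulatoryNetwork(self.graph.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (dict(self.graph.nodes(data=True))
                == dict(other.graph.nodes(data=True))
                and {(u, v): d for u, v, d in self.graph.edges(data=True)}
                == {(u, v): d for u, v, d in other.graph.edges(data=True)})

    # -- export ------------------------------------------------------------

    def to_graphml(self, path) -> None:
        g = nx.DiGraph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(n, **{k: v for k, v in d.items() if v is not None})
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, **{k: val for k, val in d.items()
                                if val is not None})
        nx.write_graphml(g, path)

    def to_sif(self, path) -> None:
        """Simple interaction format: source, relation tag, target.

        The relation tag encodes the correlation sign: ``activates`` for
        positive, ``represses`` for negative.
        """
        with open(path, "w") as fh:
            for u, v, d in sorted(self.graph.edges(data=True)):
                tag = "activates" if d.get("sign", 1) >= 0 else "represses"
                fh.write(f"{u}\t{tag}\t{v}\n")
            for n in sorted(nx.isolates(self.graph)):
                fh.write(f"{n}\n")


def load_graphml(path) -> RegulatoryNetwork:
    return RegulatoryNetwork(nx.read_graphml(path))
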