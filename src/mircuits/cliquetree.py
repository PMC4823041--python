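"""Moralization, minimum-fill triangulation and junction trees.

The topological pathway test decomposes each (augmented) pathway graph
into a tree of maximal cliques: the directed graph is moralized
(co-parents married, directions dropped), triangulated with a
deterministic minimum-fill heuristic, and its maximal cliques are joined
by a maximum-weight spanning tree on separator sizes, which for a chordal
graph yields a junction tree satisfying the running intersection
property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


def moralize(g: nx.DiGraph) -> nx.Graph:
    """Marry co-parents and drop edge directions."""
    moral = nx.Graph()
    moral.add_nodes_from(g.nodes)
    moral.add_edges_from((u, v) for u, v in g.edges if u != v)
    for node in g:
        parents = sorted(g.predecessors(node))
        for i, p in enumerate(parents):
            for q in parents[i + 1:]:
                moral.add_edge(p, q)
    return moral


def triangulate(g: nx.Graph) -> nx.Graph:
    """Add chords via the minimum-fill elimination heuristic.

    At each step the node whose elimination adds the fewest fill-in edges
    is removed (ties broken by node ID), its neighbourhood completed.
    Deterministic, and the identity on already-chordal graphs when the
    min-fill choice has fill-in zero (always true for chordal graphs,
    which admit a perfect elimination ordering).
    """
    h = nx.Graph(g)
    h.remove_edges_from(nx.selfloop_edges(h))
    work = nx.Graph(h)
    while work.number_of_nodes() > 0:
        best_node, best_fill = None, None
        for node in sorted(work.nodes):
            nbrs = list(work.neighbors(node))
            fill = [
                (u, v)
                for i, u in enumerate(nbrs)
                for v in nbrs[i + 1:]
                if not work.has_edge(u, v)
            ]
            if best_fill is None or len(fill) < len(best_fill):
                best_node, best_fill = node, fill
                if not fill:
                    break
        h.add_edges_from(best_fill)
        work.add_edges_from(best_fill)
        work.remove_node(best_node)
    return h


def moralize_and_triangulate(g: nx.DiGraph) -> nx.Graph:
    return triangulate(moralize(g))


@dataclass
class JunctionTree:
    """Tree over the maximal cliques of a chordal graph.

    ``cliques`` is a sorted list of frozensets; ``tree`` is an undirected
    graph on clique indices whose edges carry the separator sets.
    """

    cliques: list[frozenset[str]]
    tree: nx.Graph = field(repr=False)

    @property
    def n_cliques(self) -> int:
        return len(self.cliques)

    def separator(self, i: int, j: int) -> frozenset[str]:
        return self.tree.edges[i, j]["separator"]

    def covers_edges_of(self, g: nx.Graph) -> bool:
        """Every edge of ``g`` lies inside at least one clique."""
        return all(
            any(u in c and v in c for c in self.cliques)
            for u, v in g.edges
            if u != v
        )

    def has_running_intersection(self) -> bool:
        """For each node, the cliques containing it induce a subtree."""
        nodes = set().union(*self.cliques) if self.cliques else set()
        for node in nodes:
            holding = [i for i, c in enumerate(self.cliques) if node in c]
            sub = self.tree.subgraph(holding)
            if len(holding) > 1 and not nx.is_connected(sub):
                return False
        return True

    def simple_paths(self, max_length: int):
        """Yield every simple clique path of 1..max_length cliques.

        In a tree the path between two cliques is unique; single cliques
        count as length-1 paths.  Each path is a tuple of clique indices,
        yielded once with its lexicographically smaller orientation.
        """
        for i in range(self.n_cliques):
            yield (i,)
        for comp in nx.connected_components(self.tree):
            members = sorted(comp)
            for a, i in enumerate(members):
                for j in members[a + 1:]:
                    path = nx.shortest_path(self.tree, i, j)
                    if len(path) <= max_length:
                        yield tuple(path)


def junction_tree(g: nx.Graph) -> JunctionTree:
    """Build a junction tree from a chordal undirected graph.

    Maximal cliques are connected by a maximum-weight spanning tree on
    pairwise separator sizes (deterministic tie-break on clique indices),
    which satisfies the running intersection property for chordal inputs.
    """
    if g.number_of_nodes() == 0:
        return JunctionTree([], nx.Graph())
    if not nx.is_chordal(g):
        raise ValueError("junction_tree requires a chordal graph")
    cliques = sorted({frozenset(c) for c in nx.chordal_graph_cliques(g)},
                     key=lambda c: sorted(c))
    tree = nx.Graph()
    tree.add_nodes_from(range(len(cliques)))
    weighted = []
    for i in range(len(cliques)):
        for j in range(i + 1, len(cliques)):
            sep = cliques[i] & cliques[j]
            if sep:
                weighted.append((i, j, len(sep)))
    # Kruskal on (-|separator|, i, j) for a deterministic forest
    weighted.sort(key=lambda e: (-e[2], e[0], e[1]))
    uf = {i: i for i in range(len(cliques))}

    def find(x):
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    for i, j, _w in weighted:
        ri, rj = find(i), find(j)
        if ri != rj:
            uf[ri] = rj
            tree.add_edge(i, j, separator=cliques[i] & cliques[j])
    # cliques in disconnected components stay isolated tree nodes
    return JunctionTree(cliques, tree)


def pathway_junction_tree(directed: nx.DiGraph) -> JunctionTree:
    """Moralize + triangulate + junction tree in one step."""
    return junction_tree(moralize_and_triangulate(directed))
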