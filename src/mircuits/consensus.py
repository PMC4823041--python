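"""Cross-cohort consensus: circuit intersection, merged networks and the
"child" network of shared nodes plus first neighbours.

Two cohorts are analysed in parallel; a relationship is *shared* when the
same ordered node pair carries the same correlation sign in both cohorts'
networks.  The child network is the merged-network subgraph induced by the
nodes incident to shared relationships together with their first
neighbours — the published two-cohort consensus construction.
"""

from __future__ import annotations

from .circuits import MixedCircuit
from .networks import PROV_A, PROV_B, PROV_BOTH, RegulatoryNetwork


def intersect_circuits(a: list[MixedCircuit], b: list[MixedCircuit],
                       reference: str = "A") -> list[MixedCircuit]:
    """Circuits whose (topology, tf, mirna, gene) key appears in both.

    Correlation attributes are taken from the reference cohort ('A' keeps
    the first argument's values, any other value keeps the second's).
    """
    keys_b = {c.key for c in b}
    if reference == "A" or reference is None:
        return sorted((c for c in a if c.key in keys_b),
                      key=lambda c: c.key)
    keys_a = {c.key for c in a}
    return sorted((c for c in b if c.key in keys_a), key=lambda c: c.key)


def merge_networks(net_a: RegulatoryNetwork, net_b: RegulatoryNetwork,
                   reference: str = "A") -> RegulatoryNetwork:
    """Union of two cohort networks with edge provenance A/B/both.

    Edge identity is the (ordered pair, sign) relationship; when both
    cohorts supply an edge, the reference cohort's weight is kept.
    """
    ref_first = reference in ("A", None)
    first, second = (net_a, net_b) if ref_first else (net_b, net_a)
    prov_first = PROV_A if ref_first else PROV_B
    prov_second = PROV_B if ref_first else PROV_A

    merged = RegulatoryNetwork()
    for net in (first, second):
        for n, d in net.nodes(data=True):
            if n not in merged.nodes:
                merged.graph.add_node(n, **d)
    shared = net_a.signed_pairs() & net_b.signed_pairs()
    for u, v, d in first.edges(data=True):
        prov = PROV_BOTH if (u, v, d["sign"]) in shared else prov_first
        merged.graph.add_edge(u, v, sign=d["sign"], weight=d["weight"],
                              provenance=prov)
    for u, v, d in second.edges(data=True):
        if merged.graph.has_edge(u, v) and \
                merged.graph.edges[u, v]["sign"] == d["sign"]:
            continue  # reference cohort's attributes win
        prov = PROV_BOTH if (u, v, d["sign"]) in shared else prov_second
        if merged.graph.has_edge(u, v):
            # same pair, opposite sign: keep the larger |weight| variant
            if abs(merged.graph.edges[u, v]["weight"]) >= abs(d["weight"]):
                continue
        merged.graph.add_edge(u, v, sign=d["sign"], weight=d["weight"],
                              provenance=prov)
    return merged


def shared_relationship_nodes(net_a: RegulatoryNetwork,
                              net_b: RegulatoryNetwork) -> set[str]:
    """Nodes incident to at least one relationship present in both cohorts
    (same ordered pair, same sign)."""
    shared = net_a.signed_pairs() & net_b.signed_pairs()
    nodes: set[str] = set()
    for u, v, _sign in shared:
        nodes.add(u)
        nodes.add(v)
    return nodes


def extract_child_network(merged: RegulatoryNetwork, seeds: set[str],
                          ) -> RegulatoryNetwork:
    """Induced subnetwork on the seeds plus their first neighbours.

    Seed nodes carry a ``seed`` attribute in the output; edge attributes
    are those of the merged network (hence of the reference cohort where
    both cohorts supplied the relationship).
    """
    unknown = sorted(s for s in seeds if s not in merged.nodes)
    if unknown:
        raise ValueError(f"unknown seed nodes: {unknown}")
    keep: set[str] = set(seeds)
    for s in seeds:
        keep |= merged.neighbors(s)
    child = merged.induced(keep)
    for n in child.nodes:
        child.graph.nodes[n]["seed"] = n in seeds
    return child
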