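"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own data structures and algorithms:
paths are enumerated by plain recursion over an edge list, AUROC by
explicit pairwise comparison.
"""

from __future__ import annotations

import numpy as np

from slapnet.graph import SemanticGraph, canonical_edge
from slapnet.schema import Schema


def naive_simple_paths(graph, source, target, max_length, excluded=()):
    """Exhaustive recursive enumeration of simple paths (no pruning).

    Works from the public edge iterator only; returns a set of
    (nodes tuple, edge_types tuple).
    """
    adj: dict[str, list[tuple[str, str]]] = {}
    for u, etype, v in graph.edges():
        adj.setdefault(u, []).append((etype, v))
        adj.setdefault(v, []).append((etype, u))
    excluded = {canonical_edge(*e) for e in excluded}
    results = set()

    def rec(node, nodes, types):
        if len(types) > max_length:
            return
        if node == target and types:
            results.add((tuple(nodes), tuple(types)))
            return
        if len(types) == max_length:
            return
        for etype, nbr in adj.get(node, ()):
            if nbr in nodes:
                continue
            if canonical_edge(node, etype, nbr) in excluded:
                continue
            rec(nbr, nodes + [nbr], types + [etype])

    rec(source, [source], [])
    return results


def random_typed_graph(seed: int, max_nodes: int = 50) -> SemanticGraph:
    """A random small typed graph over a 3-class, 4-edge-type schema."""
    rng = np.random.default_rng(seed)
    schema = Schema(
        node_classes=frozenset({"A", "B", "C"}),
        edge_types={
            "ab": frozenset({"A", "B"}),
            "bc": frozenset({"B", "C"}),
            "ac": frozenset({"A", "C"}),
            "bb": frozenset({"B"}),
        },
    )
    g = SemanticGraph(schema=schema)
    n = int(rng.integers(8, max_nodes + 1))
    classes = rng.choice(["A", "B", "C"], size=n)
    for i, cls in enumerate(classes):
        g.add_node(f"n{i}", str(cls))
    by_class = {c: g.nodes(c) for c in "ABC"}
    n_edges = int(rng.integers(n, 3 * n))
    for _ in range(n_edges):
        etype = str(rng.choice(["ab", "bc", "ac", "bb"]))
        endpoint_classes = sorted(g.schema.edge_types[etype])
        ca, cb = endpoint_classes[0], endpoint_classes[-1]
        if not by_class[ca] or not by_class[cb]:
            continue
        u = by_class[ca][int(rng.integers(len(by_class[ca])))]
        v = by_class[cb][int(rng.integers(len(by_class[cb])))]
        if u != v:
            g.add_edge(u, etype, v)
    return g


def pairwise_auroc(pos_scores, neg_scores) -> float:
    """AUROC by brute-force comparison of every (positive, negative) pair."""
    wins = ties = 0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))
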