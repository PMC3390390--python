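"""Typed heterogeneous network container and TSV I/O.

The network is an undirected graph whose nodes carry a single class label
and whose edges carry an edge-type label. Per edge type the graph is
simple: duplicate (u, type, v) rows collapse into one edge, while the same
node pair may be joined by edges of several different types. Self-loops
are dropped at load time (the traversal model gives them no meaning).

The central primitive is the *typed adjacency*: for every node, a mapping
edge type -> set of neighbors. ``type_degree(node, t)`` — the number of
distinct neighbors reachable from ``node`` via edges of type ``t`` — is
the denominator of every traversal probability, so the container is built
around it rather than wrapping a general-purpose graph library.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import GraphValidationError, NotMappedError
from .schema import Schema

__all__ = [
    "SemanticGraph",
    "canonical_edge",
    "load_graph",
    "write_graph",
    "load_pairs",
    "write_pairs",
]

logger = logging.getLogger(__name__)

Edge = tuple[str, str, str]  # (u, edge_type, v), canonical: u <= v


def canonical_edge(u: str, edge_type: str, v: str) -> Edge:
    """Canonical undirected form of an edge: endpoints in sorted order."""
    return (u, edge_type, v) if u <= v else (v, edge_type, u)


@dataclass
class SemanticGraph:
    """Undirected typed multigraph validated against a :class:`Schema`."""

    schema: Schema
    node_class: dict[str, str] = field(default_factory=dict)
    # node -> edge type -> set of neighbors
    _adj: dict[str, dict[str, set[str]]] = field(default_factory=dict, repr=False)

    # -- construction -------------------------------------------------

    def add_node(self, node: str, node_class: str) -> None:
        if node_class not in self.schema.node_classes:
            raise GraphValidationError(
                f"node {node!r}: class {node_class!r} is not declared in the schema"
            )
        existing = self.node_class.get(node)
        if existing is not None and existing != node_class:
            raise GraphValidationError(
                f"node {node!r} declared with conflicting classes {existing!r} and {node_class!r}"
            )
        self.node_class[node] = node_class
        self._adj.setdefault(node, {})

    def add_edge(self, u: str, edge_type: str, v: str) -> bool:
        """Add an undirected typed edge; returns False if it already existed.

        Self-loops are silently dropped (with a log warning), matching the
        traversal model in which a step always moves to a different node.
        """
        if u == v:
            logger.warning("dropping self-loop %r on node %r", edge_type, u)
            return False
        for node in (u, v):
            if node not in self.node_class:
                raise GraphValidationError(f"edge references undeclared node {node!r}")
        if not self.schema.allows_edge(edge_type, self.node_class[u], self.node_class[v]):
            raise GraphValidationError(
                f"edge type {edge_type!r} may not connect classes "
                f"{self.node_class[u]!r} and {self.node_class[v]!r} "
                f"(edge {u!r}-{v!r})"
            )
        bucket = self._adj[u].setdefault(edge_type, set())
        if v in bucket:
            return False
        bucket.add(v)
        self._adj[v].setdefault(edge_type, set()).add(u)
        return True

    # -- queries -------------------------------------------------------

    def __contains__(self, node: str) -> bool:
        return node in self.node_class

    @property
    def n_nodes(self) -> int:
        return len(self.node_class)

    @property
    def n_edges(self) -> int:
        return sum(1 for _ in self.edges())

    def nodes(self, node_class: str | None = None) -> list[str]:
        """Sorted node ids, optionally restricted to one class."""
        if node_class is None:
            return sorted(self.node_class)
        return sorted(n for n, c in self.node_class.items() if c == node_class)

    def class_of(self, node: str) -> str:
        try:
            return self.node_class[node]
        except KeyError:
            raise NotMappedError(node) from None

    def edges(self) -> Iterator[Edge]:
        """Iterate every edge once, in canonical (u <= v) orientation."""
        for u in self.node_class:
            for etype, nbrs in self._adj[u].items():
                for v in nbrs:
                    if u <= v:
                        yield (u, etype, v)

    def has_edge(self, u: str, edge_type: str, v: str) -> bool:
        return v in self._adj.get(u, {}).get(edge_type, ())

    def type_degree(self, node: str, edge_type: str) -> int:
        """Number of distinct neighbors of ``node`` via edges of ``edge_type``.

        An unknown edge type yields 0 (no such neighbors); an unknown node
        raises :class:`NotMappedError`.
        """
        if node not in self.node_class:
            raise NotMappedError(node)
        return len(self._adj[node].get(edge_type, ()))

    def neighbors(self, node: str) -> dict[str, set[str]]:
        """The typed adjacency of ``node``: edge type -> neighbor set."""
        if node not in self.node_class:
            raise NotMappedError(node)
        return self._adj[node]

    def direct_edges(self, u: str, v: str) -> set[Edge]:
        """All edges (of any type) directly joining ``u`` and ``v``."""
        if u not in self.node_class or v not in self.node_class:
            return set()
        return {
            canonical_edge(u, etype, v)
            for etype, nbrs in self._adj[u].items()
            if v in nbrs
        }

    # -- validation & reporting ---------------------------------------

    def validate(self) -> None:
        """Re-check every invariant from scratch.

        Verifies endpoint declaration, schema conformance of every edge,
        absence of self-loops, and that the typed adjacency is exactly
        symmetric (u lists v iff v lists u, per type).
        """
        for node, cls in self.node_class.items():
            if cls not in self.schema.node_classes:
                raise GraphValidationError(f"node {node!r} has undeclared class {cls!r}")
        for u, by_type in self._adj.items():
            if u not in self.node_class:
                raise GraphValidationError(f"adjacency lists undeclared node {u!r}")
            for etype, nbrs in by_type.items():
                for v in nbrs:
                    if u == v:
                        raise GraphValidationError(f"self-loop {etype!r} on {u!r}")
                    if v not in self.node_class:
                        raise GraphValidationError(
                            f"edge {u!r}-{etype}-{v!r} references undeclared node {v!r}"
                        )
                    if not self.schema.allows_edge(
                        etype, self.node_class[u], self.node_class[v]
                    ):
                        raise GraphValidationError(
                            f"edge {u!r}-{etype}-{v!r} violates schema class constraints"
                        )
                    if u not in self._adj.get(v, {}).get(etype, ()):
                        raise GraphValidationError(
                            f"asymmetric adjacency: {u!r}-{etype}-{v!r} lacks the reverse entry"
                        )

    def summary(self) -> dict:
        """Load report: node counts per class and edge counts per type."""
        nodes = Counter(self.node_class.values())
        edges = Counter(etype for _, etype, _ in self.edges())
        return {
            "n_nodes": self.n_nodes,
            "n_edges": sum(edges.values()),
            "nodes_per_class": dict(sorted(nodes.items())),
            "edges_per_type": dict(sorted(edges.items())),
        }

    def to_networkx(self):
        """Convert to a ``networkx.MultiGraph`` (keys = edge types)."""
        import networkx as nx

        g = nx.MultiGraph()
        for node, cls in self.node_class.items():
            g.add_node(node, node_class=cls)
        for u, etype, v in self.edges():
            g.add_edge(u, v, key=etype, edge_type=etype)
        return g


# -- file I/O ----------------------------------------------------------


def load_graph(
    node_table: str | Path,
    edge_table: str | Path,
    schema: Schema,
    weight_filters: Mapping[str, float] | None = None,
) -> SemanticGraph:
    """Load a network from node and edge TSV tables.

    The node table has a header row and columns ``id<TAB>class``; the edge
    table has ``source<TAB>type<TAB>target`` with an optional fourth
    numeric ``weight`` column. Edge direction in the file is ignored and
    duplicate identical edges collapse. ``weight_filters`` optionally maps
    an edge type to a maximum weight: rows of that type whose weight is
    present and >= the cutoff are skipped (e.g. keeping only binding
    affinities below a threshold); rows without a weight always pass.
    """
    graph = SemanticGraph(schema=schema)

    node_table, edge_table = Path(node_table), Path(edge_table)
    with node_table.open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise GraphValidationError(f"{node_table}: empty node table")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise GraphValidationError(f"{node_table}:{lineno}: expected id<TAB>class")
            try:
                graph.add_node(parts[0], parts[1])
            except GraphValidationError as exc:
                raise GraphValidationError(f"{node_table}:{lineno}: {exc}") from exc

    missing: set[str] = set()
    with edge_table.open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise GraphValidationError(f"{edge_table}: empty edge table")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise GraphValidationError(
                    f"{edge_table}:{lineno}: expected source<TAB>type<TAB>target"
                )
            source, etype, target = parts[:3]
            if weight_filters and etype in weight_filters and len(parts) >= 4 and parts[3]:
                try:
                    weight = float(parts[3])
                except ValueError as exc:
                    raise GraphValidationError(
                        f"{edge_table}:{lineno}: non-numeric weight {parts[3]!r}"
                    ) from exc
                if weight >= weight_filters[etype]:
                    continue
            absent = [n for n in (source, target) if n not in graph]
            if absent:
                missing.update(absent)
                continue
            try:
                graph.add_edge(source, etype, target)
            except GraphValidationError as exc:
                raise GraphValidationError(f"{edge_table}:{lineno}: {exc}") from exc
    if missing:
        raise GraphValidationError(
            f"{edge_table}: edges reference nodes absent from the node table: "
            f"{sorted(missing)[:20]}"
        )
    logger.info("loaded graph: %s", graph.summary())
    return graph


def write_graph(
    graph: SemanticGraph, node_table: str | Path, edge_table: str | Path
) -> None:
    """Write the network back to the two-table TSV format (sorted rows)."""
    with Path(node_table).open("w", encoding="utf-8") as fh:
        fh.write("id\tclass\n")
        for node in graph.nodes():
            fh.write(f"{node}\t{graph.node_class[node]}\n")
    with Path(edge_table).open("w", encoding="utf-8") as fh:
        fh.write("source\ttype\ttarget\n")
        for u, etype, v in sorted(graph.edges()):
            fh.write(f"{u}\t{etype}\t{v}\n")


def load_pairs(path: str | Path) -> list[tuple[str, str, int]]:
    """Load a pair list TSV: ``source<TAB>target<TAB>label`` with label in {0, 1}.

    Node ids need not be present in any graph; presence is resolved at
    scoring time (unmapped pairs are reported, not rejected here).
    """
    pairs: list[tuple[str, str, int]] = []
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or parts[2] not in ("0", "1"):
                raise GraphValidationError(
                    f"{path}:{lineno}: expected source<TAB>target<TAB>label(0|1)"
                )
            pairs.append((parts[0], parts[1], int(parts[2])))
    return pairs


def write_pairs(pairs: Iterable[tuple[str, str, int]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tlabel\n")
        for s, t, label in pairs:
            fh.write(f"{s}\t{t}\t{label}\n")
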