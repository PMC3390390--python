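"""Bounded-length simple-path enumeration and semantic path patterns.

Association between two nodes is read off the *paths* connecting them.
This module enumerates every simple path up to a length bound (default 3
edges) between a query pair, optionally refusing to traverse particular
edges (used to remove a known direct link so that a score reflects only
neighborhood evidence), and canonicalizes each path's *pattern*: the
alternating sequence of node classes and edge types read from the query
end, which abstracts the specific nodes away.

Enumeration is a depth-first search pruned by a breadth-first distance
map from the target: a branch is abandoned as soon as the remaining
length budget cannot bridge the (exclusion-free, hence lower-bound)
distance back to the target. Output order is deterministic — sorted by
(length, pattern signature, node sequence) — so downstream floating-point
sums are reproducible bit for bit.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import GraphValidationError, NotMappedError
from .graph import Edge, SemanticGraph, canonical_edge

__all__ = ["Path", "pattern_signature", "enumerate_paths", "group_by_pattern"]

SIGNATURE_SEP = "|"


@dataclass(frozen=True)
class Path:
    """A simple path: m node ids joined by m-1 typed edges."""

    nodes: tuple[str, ...]
    edge_types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.edge_types) + 1 or len(self.edge_types) < 1:
            raise ValueError("a path needs m nodes and m-1 edge types, m >= 2")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"path repeats a node: {self.nodes}")

    @property
    def length(self) -> int:
        """Number of edges."""
        return len(self.edge_types)

    @property
    def source(self) -> str:
        return self.nodes[0]

    @property
    def target(self) -> str:
        return self.nodes[-1]

    def reversed(self) -> "Path":
        return Path(tuple(reversed(self.nodes)), tuple(reversed(self.edge_types)))

    def steps(self) -> Iterable[tuple[str, str, str]]:
        """Yield (from_node, edge_type, to_node) in traversal order."""
        for i, etype in enumerate(self.edge_types):
            yield self.nodes[i], etype, self.nodes[i + 1]


def pattern_signature(path: Path, graph: SemanticGraph) -> str:
    """Semantic signature of a path, read from the source end.

    Alternates node-class and edge-type labels joined by ``|``, e.g.
    ``Compound|bind|Target|hasGO|GOTerm|hasGO|Target``. Two paths through
    different nodes but the same class/type alternation share one
    signature. Signatures are directional (not symmetrized): patterns are
    read from the query side.
    """
    parts: list[str] = []
    for node, etype in zip(path.nodes, path.edge_types):
        if node not in graph:
            raise GraphValidationError(f"path node {node!r} missing from graph")
        parts.append(graph.class_of(node))
        parts.append(etype)
    last = path.nodes[-1]
    if last not in graph:
        raise GraphValidationError(f"path node {last!r} missing from graph")
    parts.append(graph.class_of(last))
    return SIGNATURE_SEP.join(parts)


def _distances_to(graph: SemanticGraph, target: str, cap: int) -> dict[str, int]:
    """BFS hop distances to ``target`` (type-blind), capped at ``cap``."""
    dist = {target: 0}
    frontier = deque([target])
    while frontier:
        node = frontier.popleft()
        d = dist[node]
        if d >= cap:
            continue
        for nbrs in graph.neighbors(node).values():
            for nbr in nbrs:
                if nbr not in dist:
                    dist[nbr] = d + 1
                    frontier.append(nbr)
    return dist


def enumerate_paths(
    graph: SemanticGraph,
    source: str,
    target: str,
    max_length: int = 3,
    excluded_edges: Iterable[Edge] | None = None,
) -> list[Path]:
    """All simple paths from ``source`` to ``target`` with <= ``max_length`` edges.

    Parameters
    ----------
    excluded_edges
        Edges (as ``(u, edge_type, v)`` in either orientation) that no
        returned path may traverse. Used for direct-link removal: excluding
        an edge also removes longer paths that re-use it.

    Raises
    ------
    NotMappedError
        If either endpoint is absent from the graph — an unknown entity,
        deliberately distinguishable from an empty result (no paths).
    ValueError
        If ``source == target`` or ``max_length < 1``.
    """
    for node in (source, target):
        if node not in graph:
            raise NotMappedError(node)
    if source == target:
        raise ValueError("source and target must differ")
    if max_length < 1:
        raise ValueError("max_length must be >= 1")

    excluded: frozenset[Edge] = frozenset(
        canonical_edge(*e) for e in (excluded_edges or ())
    )
    # Exclusion-free distances are a lower bound on constrained distances,
    # so pruning with them never discards a feasible branch.
    dist = _distances_to(graph, target, max_length)
    if source not in dist:
        return []

    found: list[Path] = []
    nodes_stack: list[str] = [source]
    types_stack: list[str] = []
    on_path = {source}

    def _dfs(node: str, budget: int) -> None:
        for etype in sorted(graph.neighbors(node)):
            nbrs = graph.neighbors(node)[etype]
            for nbr in sorted(nbrs):
                if nbr in on_path:
                    continue
                if excluded and canonical_edge(node, etype, nbr) in excluded:
                    continue
                if nbr == target:
                    found.append(Path(tuple(nodes_stack) + (nbr,), tuple(types_stack) + (etype,)))
                    continue
                if budget >= 2 and dist.get(nbr, max_length + 1) <= budget - 1:
                    nodes_stack.append(nbr)
                    types_stack.append(etype)
                    on_path.add(nbr)
                    _dfs(nbr, budget - 1)
                    on_path.discard(nbr)
                    nodes_stack.pop()
                    types_stack.pop()

    _dfs(source, max_length)
    found.sort(key=lambda p: (p.length, pattern_signature(p, graph), p.nodes))
    return found


def group_by_pattern(
    paths: Sequence[Path], graph: SemanticGraph
) -> dict[str, list[Path]]:
    """Partition paths by their pattern signature (group sizes sum to input size)."""
    groups: dict[str, list[Path]] = {}
    for path in paths:
        groups.setdefault(pattern_signature(path, graph), []).append(path)
    return groups
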