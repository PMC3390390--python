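"""Schema for typed heterogeneous networks.

A :class:`Schema` declares the node classes that may appear in a network and
the edge types that may connect them. Each edge type names the unordered
pair of node classes it is allowed to join (a repeated class, as in a
protein-protein interaction type, means both endpoints share one class).
Graph loading and construction validate every node and edge against the
schema, so downstream path semantics can trust the labels.

The bundled default schema (``slapnet/data/default_schema.yaml``) describes
a systems chemical-biology network with 10 node classes and 12 edge types;
it is plain YAML and meant to be copied and edited for other domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import SchemaError

__all__ = ["Schema", "load_schema", "default_schema"]


@dataclass(frozen=True)
class Schema:
    """Declared node classes and typed edge contracts of a network.

    Parameters
    ----------
    node_classes
        Set of node-class labels (unique, non-empty strings).
    edge_types
        Mapping from edge-type label to the frozenset of the one or two
        node classes that type may connect.
    """

    node_classes: frozenset[str]
    edge_types: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls in self.node_classes:
            if not isinstance(cls, str) or not cls:
                raise SchemaError(f"node class labels must be non-empty strings, got {cls!r}")
        for etype, classes in self.edge_types.items():
            if not isinstance(etype, str) or not etype:
                raise SchemaError(f"edge type labels must be non-empty strings, got {etype!r}")
            if not 1 <= len(classes) <= 2:
                raise SchemaError(
                    f"edge type {etype!r} must connect one or two classes, got {set(classes)}"
                )
            unknown = set(classes) - set(self.node_classes)
            if unknown:
                raise SchemaError(
                    f"edge type {etype!r} references undeclared node class(es): {sorted(unknown)}"
                )

    def allows_edge(self, edge_type: str, class_a: str, class_b: str) -> bool:
        """True if ``edge_type`` may connect nodes of the two given classes."""
        declared = self.edge_types.get(edge_type)
        if declared is None:
            return False
        return frozenset((class_a, class_b)) == declared

    def to_dict(self) -> dict:
        return {
            "node_classes": sorted(self.node_classes),
            "edge_types": {t: sorted(c) for t, c in sorted(self.edge_types.items())},
        }

    @classmethod
    def from_dict(cls, raw: Mapping) -> "Schema":
        try:
            classes = raw["node_classes"]
            etypes = raw["edge_types"]
        except (KeyError, TypeError) as exc:
            raise SchemaError(
                "schema must define 'node_classes' (list) and 'edge_types' (mapping)"
            ) from exc
        if not isinstance(classes, Sequence) or isinstance(classes, str):
            raise SchemaError("'node_classes' must be a list of labels")
        if len(set(classes)) != len(classes):
            dupes = sorted({c for c in classes if list(classes).count(c) > 1})
            raise SchemaError(f"duplicate node class labels: {dupes}")
        if not isinstance(etypes, Mapping):
            raise SchemaError("'edge_types' must map type label -> [classA, classB]")
        parsed: dict[str, frozenset[str]] = {}
        for etype, pair in etypes.items():
            if not isinstance(pair, Sequence) or isinstance(pair, str) or not 1 <= len(pair) <= 2:
                raise SchemaError(
                    f"edge type {etype!r} must declare one or two endpoint classes, got {pair!r}"
                )
            parsed[str(etype)] = frozenset(str(c) for c in pair)
        return cls(node_classes=frozenset(str(c) for c in classes), edge_types=parsed)


def load_schema(path: str | Path) -> Schema:
    """Load and validate a schema from a YAML file.

    Raises
    ------
    SchemaError
        If the file cannot be parsed (the error names the offending line
        where YAML reports one) or the schema violates its invariants.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise SchemaError(f"cannot read schema file {path}: {exc}") from exc
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise SchemaError(f"malformed schema file {path}{where}: {exc}") from exc
    return Schema.from_dict(raw)


def default_schema() -> Schema:
    """The bundled 10-class / 12-edge-type chemical-biology schema."""
    ref = resources.files("slapnet").joinpath("data/default_schema.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return Schema.from_dict(raw)
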