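"""Exception hierarchy shared across the package."""


class SlapError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SlapError):
    """Malformed or self-inconsistent schema definition."""


class GraphValidationError(SlapError):
    """A graph (or graph file) violates the schema or its own invariants."""


class NotMappedError(SlapError, KeyError):
    """A queried node id is absent from the network.

    Distinct from "no paths found": the entity itself is unknown, so a
    score is undefined rather than zero.
    """

    def __init__(self, node: str):
        super().__init__(node)
        self.node = node

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"node {self.node!r} is not mapped in the network"


class DegenerateFitError(SlapError):
    """A statistical fit is impossible or degenerate (e.g. zero variance)."""
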