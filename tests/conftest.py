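import numpy as np
import pytest

from slapnet.graph import SemanticGraph
from slapnet.model import SlapModel
from slapnet.schema import default_schema
from slapnet.scoring import association_score, fit_null_model, fit_pattern_stats
from slapnet.synth import SynthConfig, benchmark_from, calibration_config, generate


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def bundle0():
    """One default synthetic network with planted positives, shared read-only."""
    bundle = generate(SynthConfig(seed=0))
    bundle.graph.validate()
    return bundle


@pytest.fixture(scope="session")
def fitted0(bundle0):
    """A fitted model on bundle0, with pattern selection against benchmarks."""
    pos, dec_a = benchmark_from(bundle0, 1, seed=1000)
    _, dec_b = benchmark_from(bundle0, 1, seed=3000)
    model = SlapModel(bundle0.graph, known_positives=bundle0.positives)
    return model.fit(
        seed=7,
        n_sample_pairs=2000,
        n_null_pairs=600,
        benchmarks=[(pos, dec_a), (pos, dec_b)],
    )


class CalibrationFit:
    """Dense homogeneous network with pattern stats and null model."""

    def __init__(self, seed: int):
        self.bundle = generate(calibration_config(seed=seed))
        self.graph = self.bundle.graph
        self.drugs = self.bundle.compounds
        self.targets = self.bundle.targets
        rng = np.random.default_rng(seed + 1)
        self.stats, self.raw_scores = fit_pattern_stats(
            self.graph, self.drugs, self.targets, n_pairs=4000, seed=rng, return_raw=True
        )
        self.informative = self.stats.usable_signatures()
        from slapnet.scoring import sample_pairs

        null_pairs = sample_pairs(self.drugs, self.targets, 2000, rng)
        self.null = fit_null_model(
            [
                association_score(s, t, self.graph, self.stats, self.informative).association_score
                for s, t in null_pairs
            ]
        )


@pytest.fixture(scope="session")
def calibration_fit():
    return CalibrationFit(seed=11)


# -- small hand-wired graphs used by several modules --------------------


def free_edge_graph(schema):
    """x -bind- y with both bind degrees 1 (traversal probability 1)."""
    g = SemanticGraph(schema=schema)
    g.add_node("x", "Compound")
    g.add_node("y", "Target")
    g.add_edge("x", "bind", "y")
    return g


def one_third_chain(schema):
    """x -bind- a -bind- y with type degrees x:1, a:3, y:1."""
    g = SemanticGraph(schema=schema)
    for node in ("x", "y", "w"):
        g.add_node(node, "Compound")
    g.add_node("a", "Target")
    for node in ("x", "y", "w"):
        g.add_edge(node, "bind", "a")
    return g


def one_eighth_chain(schema):
    """D - T1 - C - T2 bind chain with every traversed type degree 2."""
    g = SemanticGraph(schema=schema)
    for node in ("D", "C", "C0"):
        g.add_node(node, "Compound")
    for node in ("T0", "T1", "T2"):
        g.add_node(node, "Target")
    g.add_edge("D", "bind", "T0")
    g.add_edge("D", "bind", "T1")
    g.add_edge("C", "bind", "T1")
    g.add_edge("C", "bind", "T2")
    g.add_edge("C0", "bind", "T2")
    return g
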