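"""Seeded generator of synthetic heterogeneous networks with planted
drug-target associations.

The generator is the package's test substrate: it emulates, at desk
scale, the structure of an integrated chemical-biology network — drugs,
targets and annotation vocabularies joined by bind / express / hasGO /
hasPathway / hasSubstructure / hasTissue / PPI-style edges — with a known
ground truth. Background edges are drawn per edge type between the two
permitted classes; by default endpoints are sampled with lognormal node
propensities (a Chung-Lu-style heavy-tailed background, since real
chem-bio networks are strongly degree-skewed and the log-normality of
random-pair association scores depends on that overdispersion).
``degree_skew=0`` recovers a homogeneous Erdős-Rényi background.

Planted positives are "missing links": for each planted (drug, target)
pair the generator wires indirect evidence routes instantiating the
informative mechanisms — shared ligand (D-bind-T'-bind-C'-bind-T), shared
GO annotation (D-bind-T'-hasGO-G-hasGO-T) and shared substructure
(D-hasSubstructure-S-hasSubstructure-D'-bind-T) — without adding the
direct bind edge (a flag adds it for direct-link-exclusion tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .graph import SemanticGraph
from .paths import Path
from .schema import Schema, default_schema
from .scoring import sample_pairs

__all__ = [
    "DEFAULT_CLASS_SIZES",
    "DEFAULT_MEAN_DEGREES",
    "SynthConfig",
    "SynthBundle",
    "generate",
    "benchmark_from",
    "calibration_config",
    "generate_drug_groups",
]

Pair = tuple[str, str]

#: node counts per class (toy scale; the real-world analogue is ~300k nodes)
DEFAULT_CLASS_SIZES: dict[str, int] = {
    "Compound": 300,
    "Target": 150,
    "GOTerm": 80,
    "Pathway": 30,
    "Substructure": 60,
    "Tissue": 20,
    "SideEffect": 40,
    "Disease": 15,
    "ChemicalOntology": 15,
    "Gene": 30,
}

#: mean background degree per node of each edge type's anchor class.
#: Chosen so a random (compound, target) pair averages about one path via
#: the binding/annotation mechanisms and a handful via expression-style
#: noise routes — the "moderate density" regime in which a few planted
#: evidence routes are recoverable.
DEFAULT_MEAN_DEGREES: dict[str, float] = {
    "bind": 1.5,
    "express": 3.5,
    "hasSubstructure": 1.5,
    "hasChemicalOntology": 0.5,
    "hasSideEffect": 1.0,
    "treat": 0.5,
    "hasGO": 2.5,
    "hasPathway": 2.5,
    "hasTissue": 2.5,
    "PPI": 1.0,
    "encode": 1.0,
    "causeDisease": 1.0,
}

#: which endpoint class the mean degree is anchored to
_ANCHOR_CLASS: dict[str, str] = {
    "bind": "Compound",
    "express": "Compound",
    "hasSubstructure": "Compound",
    "hasChemicalOntology": "Compound",
    "hasSideEffect": "Compound",
    "treat": "Compound",
    "hasGO": "Target",
    "hasPathway": "Target",
    "hasTissue": "Target",
    "PPI": "Target",
    "encode": "Gene",
    "causeDisease": "Gene",
}

_ID_PREFIX: dict[str, str] = {
    "Compound": "C",
    "Target": "T",
    "GOTerm": "GO",
    "Pathway": "PW",
    "Substructure": "SU",
    "Tissue": "TI",
    "SideEffect": "SE",
    "Disease": "DI",
    "ChemicalOntology": "CO",
    "Gene": "GN",
}

MECHANISMS = ("shared_ligand", "shared_go", "shared_substructure")


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of one synthetic network.

    ``class_sizes`` gives the node count per class; ``mean_degrees`` the
    background mean degree per anchor-class node and edge type;
    ``n_planted`` and ``planting_strength`` (evidence routes per planted
    pair, 0-10) control the ground truth; ``degree_skew`` is the sigma of
    the lognormal node propensities (0 = homogeneous background), either
    one value for all classes or a mapping node class -> sigma (per-pair
    path counts scale with the product of the endpoint propensities, so
    skewing Compound/Target more than the annotation vocabularies yields
    the overdispersed, log-normal-like connectivity of real networks). The
    seed is mandatory — every byte of the output is a function of the
    config.
    """

    seed: int
    class_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    mean_degrees: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MEAN_DEGREES))
    n_planted: int = 100
    planting_strength: int = 3
    mechanism_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    add_direct_edges: bool = False
    degree_skew: float | Mapping[str, float] = 0.8

    def skew_for(self, node_class: str) -> float:
        if isinstance(self.degree_skew, Mapping):
            return float(self.degree_skew.get(node_class, 0.0))
        return float(self.degree_skew)

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.class_sizes.values()):
            raise ValueError("class sizes must be >= 0")
        if not 0 <= self.planting_strength <= 10:
            raise ValueError("planting strength must be in 0..10")
        if self.n_planted < 0:
            raise ValueError("n_planted must be >= 0")


@dataclass
class SynthBundle:
    """A generated network plus its ground truth."""

    graph: SemanticGraph
    positives: list[Pair]
    evidence: dict[Pair, list[Path]]
    config: SynthConfig

    @property
    def compounds(self) -> list[str]:
        return self.graph.nodes("Compound")

    @property
    def targets(self) -> list[str]:
        return self.graph.nodes("Target")

    def decoy_pool(self) -> list[Pair]:
        """All (compound, target) pairs that were not planted."""
        planted = set(self.positives)
        return [
            (c, t)
            for c in self.compounds
            for t in self.targets
            if (c, t) not in planted
        ]


def _node_ids(cls: str, n: int) -> list[str]:
    return [f"{_ID_PREFIX[cls]}{i:04d}" for i in range(n)]


def _sample_background_edges(
    graph: SemanticGraph,
    rng: np.random.Generator,
    nodes_by_class: Mapping[str, list[str]],
    mean_degrees: Mapping[str, float],
    schema: Schema,
    config: SynthConfig,
) -> None:
    """Draw background edges per type with weighted endpoint sampling."""
    weights: dict[str, float] = {}
    for cls in sorted(nodes_by_class):
        sigma = config.skew_for(cls)
        draws = (
            rng.lognormal(0.0, sigma, len(nodes_by_class[cls]))
            if sigma > 0
            else np.ones(len(nodes_by_class[cls]))
        )
        weights.update(zip(nodes_by_class[cls], map(float, draws)))
    for etype in sorted(mean_degrees):
        classes = schema.edge_types.get(etype)
        if classes is None:
            raise ValueError(f"mean degree given for unknown edge type {etype!r}")
        anchor = _ANCHOR_CLASS.get(etype, sorted(classes)[0])
        other = next(iter(classes - {anchor}), anchor)
        a_nodes, b_nodes = nodes_by_class.get(anchor, []), nodes_by_class.get(other, [])
        if not a_nodes or not b_nodes:
            continue
        n_edges = int(round(len(a_nodes) * mean_degrees[etype]))
        if anchor == other:
            n_edges //= 2
            max_edges = len(a_nodes) * (len(a_nodes) - 1) // 2
        else:
            max_edges = len(a_nodes) * len(b_nodes)
        if n_edges > max_edges:
            raise ValueError(
                f"edge type {etype!r}: requested {n_edges} edges exceeds the "
                f"{max_edges} possible between {anchor} and {other}"
            )
        pa = np.array([weights[n] for n in a_nodes])
        pb = np.array([weights[n] for n in b_nodes])
        pa, pb = pa / pa.sum(), pb / pb.sum()
        added, attempts = 0, 0
        while added < n_edges and attempts < 30 * n_edges + 100:
            attempts += 1
            u = a_nodes[int(rng.choice(len(a_nodes), p=pa))]
            v = b_nodes[int(rng.choice(len(b_nodes), p=pb))]
            if u != v and graph.add_edge(u, etype, v):
                added += 1


def _other(rng: np.random.Generator, pool: Sequence[str], *avoid: str) -> str:
    while True:
        pick = pool[int(rng.integers(len(pool)))]
        if pick not in avoid:
            return pick


def _plant_route(
    graph: SemanticGraph,
    rng: np.random.Generator,
    mechanism: str,
    drug: str,
    target: str,
    nodes_by_class: Mapping[str, list[str]],
) -> Path:
    """Wire one indirect evidence route for (drug, target); returns it."""
    if mechanism == "shared_ligand":
        t2 = _other(rng, nodes_by_class["Target"], target)
        c2 = _other(rng, nodes_by_class["Compound"], drug)
        graph.add_edge(drug, "bind", t2)
        graph.add_edge(c2, "bind", t2)
        graph.add_edge(c2, "bind", target)
        return Path((drug, t2, c2, target), ("bind", "bind", "bind"))
    if mechanism == "shared_go":
        t2 = _other(rng, nodes_by_class["Target"], target)
        go = nodes_by_class["GOTerm"][int(rng.integers(len(nodes_by_class["GOTerm"])))]
        graph.add_edge(drug, "bind", t2)
        graph.add_edge(t2, "hasGO", go)
        graph.add_edge(target, "hasGO", go)
        return Path((drug, t2, go, target), ("bind", "hasGO", "hasGO"))
    if mechanism == "shared_substructure":
        sub = nodes_by_class["Substructure"][int(rng.integers(len(nodes_by_class["Substructure"])))]
        c2 = _other(rng, nodes_by_class["Compound"], drug)
        graph.add_edge(drug, "hasSubstructure", sub)
        graph.add_edge(c2, "hasSubstructure", sub)
        graph.add_edge(c2, "bind", target)
        return Path((drug, sub, c2, target), ("hasSubstructure", "hasSubstructure", "bind"))
    raise ValueError(f"unknown planting mechanism {mechanism!r}")


def generate(config: SynthConfig, schema: Schema | None = None) -> SynthBundle:
    """Generate a synthetic network with planted positives.

    Background edges first, then ``planting_strength`` evidence routes per
    planted pair, drawn among the three informative mechanisms with the
    configured weights. Deterministic given the config (same seed -> byte
    identical node/edge tables).
    """
    schema = schema or default_schema()
    rng = np.random.default_rng(config.seed)
    nodes_by_class = {
        cls: _node_ids(cls, n) for cls, n in sorted(config.class_sizes.items()) if n > 0
    }
    graph = SemanticGraph(schema=schema)
    for cls in sorted(nodes_by_class):
        for node in nodes_by_class[cls]:
            graph.add_node(node, cls)

    _sample_background_edges(
        graph, rng, nodes_by_class, config.mean_degrees, schema, config
    )

    compounds = nodes_by_class.get("Compound", [])
    targets = nodes_by_class.get("Target", [])
    positives: list[Pair] = []
    evidence: dict[Pair, list[Path]] = {}
    if config.n_planted > 0:
        if not compounds or not targets:
            raise ValueError("planting requires Compound and Target nodes")
        positives = sample_pairs(compounds, targets, config.n_planted, rng)
        weights = np.asarray(config.mechanism_weights, dtype=float)
        weights = weights / weights.sum()
        for drug, target in positives:
            routes = []
            for _ in range(config.planting_strength):
                mech = MECHANISMS[int(rng.choice(3, p=weights))]
                routes.append(_plant_route(graph, rng, mech, drug, target, nodes_by_class))
            if config.add_direct_edges:
                graph.add_edge(drug, "bind", target)
            evidence[(drug, target)] = routes
    return SynthBundle(graph=graph, positives=positives, evidence=evidence, config=config)


def benchmark_from(
    bundle: SynthBundle, decoy_multiplier: int, seed: int
) -> tuple[list[Pair], list[Pair]]:
    """Planted positives plus a seeded decoy sample disjoint from them."""
    if decoy_multiplier < 1:
        raise ValueError("decoy multiplier must be >= 1")
    rng = np.random.default_rng(seed)
    n_decoys = decoy_multiplier * len(bundle.positives)
    decoys = sample_pairs(
        bundle.compounds, bundle.targets, n_decoys, rng, exclude=set(bundle.positives)
    )
    return list(bundle.positives), decoys


def calibration_config(seed: int) -> SynthConfig:
    """A denser configuration for null-model calibration studies.

    Emulates the regime in which the statistical model is actually fitted
    on real data — random pairs averaging tens of paths — so that the
    log-normal null is the appropriate description. Sparse "moderate
    density" defaults are for planted-link recovery instead.
    """
    return SynthConfig(
        seed=seed,
        class_sizes={**DEFAULT_CLASS_SIZES, "Compound": 250, "Target": 150},
        mean_degrees={
            **DEFAULT_MEAN_DEGREES,
            "bind": 6.0,
            "express": 7.0,
            "hasSubstructure": 4.0,
            "hasGO": 5.0,
            "hasPathway": 3.0,
            "hasTissue": 3.0,
            "PPI": 2.0,
        },
        n_planted=0,
        # homogeneous background: with every random pair averaging tens of
        # paths, the within-pair spread of z scores alone makes random-pair
        # association scores log-normal; degree skew in this dense regime
        # instead fattens the low-count left tail and spoils the fit
        degree_skew=0.0,
    )


def generate_drug_groups(
    seed: int,
    n_groups: int = 2,
    drugs_per_group: int = 10,
    targets_per_group: int = 12,
    go_terms_per_group: int = 6,
    subs_per_group: int = 6,
    binds_per_drug: int = 8,
    go_per_target: int = 3,
    subs_per_drug: int = 3,
    express_degree: float = 1.0,
    tissues_per_target: int = 1,
    n_tissues: int = 12,
    schema: Schema | None = None,
) -> tuple[SemanticGraph, dict[str, int]]:
    """A modular network whose drug groups have group-specific target wiring.

    Every group is wired identically — each group drug binds a random
    subset of its group's target panel, drugs carry substructures from the
    group's substructure pool and panel targets carry GO terms from the
    group's GO pool — so group membership is the only structure. Modules
    are tied together by global noise layers (expression edges between all
    compounds and targets, shared tissue annotations).

    The symmetry matters for the statistics: per-path scores are degree
    normalized against pattern-wide fits, so identically wired modules put
    every within-group path squarely inside its pattern's score
    distribution (about half come out with positive z) while cross-group
    pairs have almost no informative paths at all. Drugs of one group
    therefore share high association scores exactly on their own panel,
    their polypharmacology profiles correlate strongly, and cross-group
    profiles do not. A fixture wired as "groups on top of a sparse generic
    background" fails instead: the group structure is denser than the
    background, the normalization reads every group path as hub traffic
    (z < 0), and the planted signal vanishes.

    Returns the graph and the drug -> group index map.
    """
    if binds_per_drug > targets_per_group:
        raise ValueError("binds_per_drug cannot exceed targets_per_group")
    rng = np.random.default_rng(seed)
    graph = SemanticGraph(schema=schema or default_schema())
    drugs_all: list[str] = []
    targets_all: list[str] = []
    group_of: dict[str, int] = {}
    for g in range(n_groups):
        drugs = [f"C{g}{i:03d}" for i in range(drugs_per_group)]
        panel = [f"T{g}{i:03d}" for i in range(targets_per_group)]
        gos = [f"GO{g}{i:03d}" for i in range(go_terms_per_group)]
        subs = [f"SU{g}{i:03d}" for i in range(subs_per_group)]
        for node, cls in (
            [(n, "Compound") for n in drugs]
            + [(n, "Target") for n in panel]
            + [(n, "GOTerm") for n in gos]
            + [(n, "Substructure") for n in subs]
        ):
            graph.add_node(node, cls)
        for target in panel:
            for idx in rng.choice(go_terms_per_group, size=go_per_target, replace=False):
                graph.add_edge(target, "hasGO", gos[idx])
        for drug in drugs:
            group_of[drug] = g
            for idx in rng.choice(targets_per_group, size=binds_per_drug, replace=False):
                graph.add_edge(drug, "bind", panel[idx])
            for idx in rng.choice(subs_per_group, size=subs_per_drug, replace=False):
                graph.add_edge(drug, "hasSubstructure", subs[idx])
        drugs_all += drugs
        targets_all += panel
    tissues = [f"TI{i:03d}" for i in range(n_tissues)]
    for node in tissues:
        graph.add_node(node, "Tissue")
    for target in targets_all:
        for idx in rng.choice(n_tissues, size=tissues_per_target, replace=False):
            graph.add_edge(target, "hasTissue", tissues[idx])
    n_express = int(round(len(drugs_all) * express_degree))
    added, attempts = 0, 0
    while added < n_express and attempts < 30 * n_express + 100:
        attempts += 1
        u = drugs_all[int(rng.integers(len(drugs_all)))]
        v = targets_all[int(rng.integers(len(targets_all)))]
        if graph.add_edge(u, "express", v):
            added += 1
    return graph, group_of
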