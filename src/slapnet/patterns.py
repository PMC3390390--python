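"""Pattern informativeness: per-pattern benchmark AUROC and selection.

Not every semantic pattern carries signal about drug-target interaction —
some (e.g. expression-based co-pathway routes) rank known pairs no better
than chance. Each pattern is therefore assessed *standalone*: for every
benchmark pair the raw scores of its paths matching the pattern are
summed, and the pattern's AUROC is computed from how well that evidence
separates known positives from decoys. A pattern is discarded as
uninformative only when it scores at or below the threshold on *every*
supplied benchmark (removal requires agreement between benchmarks).

Orientation note: raw path scores are log-probabilities (nonpositive), so
a pair with more / stronger paths of a pattern has a more *negative* raw
sum, while a pair with no matching path sits at 0. Evidence strength is
therefore the negated raw sum, and the benchmark AUROC ranks pairs by it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import NotMappedError
from .graph import SemanticGraph
from .metrics import mann_whitney_auroc
from .paths import enumerate_paths, pattern_signature
from .scoring import raw_path_score

__all__ = [
    "pair_pattern_scores",
    "pattern_pair_score",
    "pattern_scores_table",
    "pattern_auroc",
    "PatternReport",
    "evaluate_patterns",
    "select_informative",
]

Pair = tuple[str, str]


def pair_pattern_scores(
    pair: Pair,
    graph: SemanticGraph,
    max_length: int = 3,
    exclude_direct: bool = False,
) -> dict[str, float]:
    """Raw-score sum per pattern signature for one pair.

    Unmapped pairs yield an empty mapping (score 0 for every pattern).
    """
    source, target = pair
    excluded = graph.direct_edges(source, target) if exclude_direct else None
    try:
        paths = enumerate_paths(
            graph, source, target, max_length=max_length, excluded_edges=excluded
        )
    except NotMappedError:
        return {}
    sums: dict[str, float] = {}
    for path in paths:
        sig = pattern_signature(path, graph)
        sums[sig] = sums.get(sig, 0.0) + raw_path_score(path, graph)
    return sums


def pattern_pair_score(
    pair: Pair,
    signature: str,
    graph: SemanticGraph,
    max_length: int = 3,
    exclude_direct: bool = False,
) -> float:
    """Sum of raw scores of the pair's paths matching ``signature`` (0 if none)."""
    return pair_pattern_scores(
        pair, graph, max_length=max_length, exclude_direct=exclude_direct
    ).get(signature, 0.0)


def pattern_scores_table(
    pairs: Sequence[Pair],
    graph: SemanticGraph,
    max_length: int = 3,
    exclude_direct: bool = False,
) -> pd.DataFrame:
    """Pairs x patterns table of raw-score sums (one enumeration per pair)."""
    rows = [
        pair_pattern_scores(p, graph, max_length=max_length, exclude_direct=exclude_direct)
        for p in pairs
    ]
    table = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(pairs, names=["source", "target"]))
    return table.fillna(0.0).sort_index(axis=1)


def pattern_auroc(
    signature: str,
    positives: Sequence[Pair],
    decoys: Sequence[Pair],
    graph: SemanticGraph,
    max_length: int = 3,
    exclude_direct: bool = False,
) -> float:
    """Standalone AUROC of one pattern separating positives from decoys.

    Pairs are ranked by evidence strength (negated raw-score sum; no
    matching path = 0, the weakest evidence); ties contribute 1/2.
    """
    if not positives or not decoys:
        raise ValueError("both pair lists must be non-empty")
    pos = [
        -pattern_pair_score(p, signature, graph, max_length, exclude_direct) for p in positives
    ]
    neg = [
        -pattern_pair_score(p, signature, graph, max_length, exclude_direct) for p in decoys
    ]
    return mann_whitney_auroc(pos, neg)


@dataclass(frozen=True)
class PatternReport:
    """Per-pattern benchmark AUROCs and the resulting informative flag."""

    signature: str
    aurocs: tuple[float, ...]  # one per supplied benchmark
    informative: bool


def evaluate_patterns(
    signatures: Iterable[str],
    benchmarks: Sequence[tuple[Sequence[Pair], Sequence[Pair]]],
    graph: SemanticGraph,
    threshold: float = 0.55,
    max_length: int = 3,
    exclude_direct: bool = False,
) -> dict[str, PatternReport]:
    """Evaluate every pattern on every (positives, decoys) benchmark.

    Enumerates each benchmark pair once and scores all patterns from that
    single pass. A pattern is informative unless its AUROC is <= threshold
    on all benchmarks.
    """
    if not benchmarks:
        raise ValueError("at least one (positives, decoys) benchmark is required")
    signatures = sorted(set(signatures))
    tables = []
    for positives, decoys in benchmarks:
        if not positives or not decoys:
            raise ValueError("benchmark pair lists must be non-empty")
        pos_tab = pattern_scores_table(list(positives), graph, max_length, exclude_direct)
        neg_tab = pattern_scores_table(list(decoys), graph, max_length, exclude_direct)
        tables.append((pos_tab, neg_tab))
    reports: dict[str, PatternReport] = {}
    for sig in signatures:
        aurocs = []
        for pos_tab, neg_tab in tables:
            pos = -pos_tab[sig].to_numpy() if sig in pos_tab.columns else [0.0] * len(pos_tab)
            neg = -neg_tab[sig].to_numpy() if sig in neg_tab.columns else [0.0] * len(neg_tab)
            aurocs.append(mann_whitney_auroc(pos, neg))
        informative = any(a > threshold for a in aurocs)
        reports[sig] = PatternReport(sig, tuple(aurocs), informative)
    return reports


def select_informative(
    reports: Mapping[str, PatternReport] | Iterable[PatternReport],
    threshold: float = 0.55,
) -> set[str]:
    """Signatures retained at ``threshold``.

    A pattern is removed only if its AUROC is <= threshold on every
    benchmark it was evaluated on; monotone in the threshold.
    """
    if isinstance(reports, Mapping):
        reports = reports.values()
    return {
        r.signature for r in reports if any(a > threshold for a in r.aurocs)
    }
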