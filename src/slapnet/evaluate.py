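"""Whole-method benchmarking: association-score ranking of known pairs
against decoys, ROC / precision-recall curves, baseline link predictors,
and the decoy-ratio robustness experiment.

Baselines mirror classical link-prediction statistics over the same
enumerated paths: the number of shortest (minimum-length) paths, the
number of valid paths (z > 0 in an informative pattern), and the sum /
max / mean of raw path scores. All methods rank with the same midrank tie
convention. Direct links are removed from enumeration by default so that
every method is judged on neighborhood evidence only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_curve

from .errors import NotMappedError
from .graph import SemanticGraph
from .metrics import mann_whitney_auroc
from .paths import enumerate_paths
from .scoring import NullModel, PatternStats, p_value, sample_pairs, score_paths

__all__ = [
    "BASELINE_METHODS",
    "EvaluationRun",
    "score_table",
    "score_pairs",
    "baseline_scores",
    "roc_pr",
    "precision_at_recall",
    "ratio_experiment",
]

Pair = tuple[str, str]

BASELINE_METHODS = ("n_shortest_paths", "n_valid_paths", "raw_sum", "raw_max", "raw_mean")
_ALL_METHODS = ("slap",) + BASELINE_METHODS


def score_table(
    pairs: Sequence[Pair],
    graph: SemanticGraph,
    stats: PatternStats,
    informative: set[str] | None = None,
    exclude_direct: bool = True,
    max_length: int = 3,
    null: NullModel | None = None,
) -> pd.DataFrame:
    """Score every pair once with the association score and all baselines.

    One path enumeration per pair feeds every method. Unmapped or
    pathless pairs score 0 under every method, with the ``status`` column
    carrying the reason. Deterministic given the fitted inputs.
    """
    rows = []
    for source, target in pairs:
        row = {"source": source, "target": target}
        excluded = graph.direct_edges(source, target) if exclude_direct else None
        try:
            paths = enumerate_paths(
                graph, source, target, max_length=max_length, excluded_edges=excluded
            )
        except NotMappedError:
            paths = None
        if not paths:
            row["status"] = "no_paths" if paths == [] else "not_mapped"
            row.update({m: 0.0 for m in _ALL_METHODS})
            row["n_paths"] = 0
            if null is not None:
                row["p_value"] = 1.0
            rows.append(row)
            continue
        assoc, records = score_paths(paths, graph, stats, informative)
        raws = np.array([r.raw for r in records])
        min_len = min(p.length for p in paths)
        row["status"] = "scored"
        row["slap"] = assoc
        row["n_paths"] = len(paths)
        row["n_shortest_paths"] = float(sum(1 for p in paths if p.length == min_len))
        row["n_valid_paths"] = float(sum(1 for r in records if r.valid))
        row["raw_sum"] = float(raws.sum())
        row["raw_max"] = float(raws.max())
        row["raw_mean"] = float(raws.mean())
        if null is not None:
            row["p_value"] = p_value(assoc, null)
        rows.append(row)
    columns = ["source", "target", "status"] + list(_ALL_METHODS) + ["n_paths"] + (
        ["p_value"] if null is not None else []
    )
    return pd.DataFrame(rows, columns=columns)


def score_pairs(
    pairs: Sequence[Pair],
    graph: SemanticGraph,
    stats: PatternStats,
    informative: set[str] | None = None,
    exclude_direct: bool = True,
    max_length: int = 3,
    null: NullModel | None = None,
) -> pd.DataFrame:
    """Association score per pair (columns source, target, score, status)."""
    table = score_table(
        pairs, graph, stats, informative, exclude_direct, max_length, null
    )
    cols = ["source", "target", "slap", "status"] + (
        ["p_value"] if null is not None else []
    )
    return table[cols].rename(columns={"slap": "score"})


def baseline_scores(
    pairs: Sequence[Pair],
    graph: SemanticGraph,
    stats: PatternStats,
    informative: set[str] | None = None,
    method: str = "n_shortest_paths",
    exclude_direct: bool = True,
    max_length: int = 3,
) -> pd.DataFrame:
    """One named baseline statistic per pair."""
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown baseline {method!r}; choose from {BASELINE_METHODS}")
    table = score_table(pairs, graph, stats, informative, exclude_direct, max_length)
    return table[["source", "target", method, "status"]].rename(columns={method: "score"})


@dataclass
class EvaluationRun:
    """ROC / PR evaluation of one scoring method on one labeled pair set."""

    method: str
    scores: pd.DataFrame  # columns: score, label (plus whatever the caller added)
    auroc: float
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    precision: np.ndarray = field(repr=False)
    recall: np.ndarray = field(repr=False)
    ratio: float | None = None


def roc_pr(
    scores: Sequence[float],
    labels: Sequence[int],
    method: str = "slap",
    ratio: float | None = None,
) -> EvaluationRun:
    """ROC and precision-recall evaluation of one ranking.

    AUROC uses the midrank (Mann-Whitney) tie convention; the PR curve is
    evaluated at every score threshold. Requires both labels present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    auroc = mann_whitney_auroc(scores[labels == 1], scores[labels == 0])
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    precision, recall, _ = precision_recall_curve(labels, scores)
    table = pd.DataFrame({"score": scores, "label": labels})
    return EvaluationRun(
        method=method,
        scores=table,
        auroc=auroc,
        fpr=fpr,
        tpr=tpr,
        precision=precision,
        recall=recall,
        ratio=ratio,
    )


def precision_at_recall(run: EvaluationRun, recall_level: float) -> float:
    """Best achievable precision at recall >= ``recall_level``."""
    mask = run.recall >= recall_level
    if not mask.any():
        return 0.0
    return float(run.precision[mask].max())


def ratio_experiment(
    positives: Sequence[Pair],
    graph: SemanticGraph,
    stats: PatternStats,
    informative: set[str] | None,
    source_pool: Sequence[str],
    target_pool: Sequence[str],
    seed: int,
    multipliers: Sequence[int] = (1, 4, 8, 12),
    method: str = "slap",
    exclude_direct: bool = True,
    max_length: int = 3,
) -> dict[int, EvaluationRun]:
    """Evaluate one method at several positive:decoy ratios.

    Decoys are sampled (seeded, without replacement) from the source x
    target cross product excluding the positives; the decoy sets are
    *nested* across multipliers (the 1x decoys are a prefix of the 12x
    decoys), so ratio effects are not confounded by resampling. Each pair
    is scored once.
    """
    if method not in _ALL_METHODS:
        raise ValueError(f"unknown method {method!r}")
    positives = list(positives)
    rng = np.random.default_rng(seed)
    n_max = max(multipliers) * len(positives)
    decoys = sample_pairs(source_pool, target_pool, n_max, rng, exclude=set(positives))
    table = score_table(
        positives + decoys, graph, stats, informative, exclude_direct, max_length
    )
    pos_scores = table[method].to_numpy()[: len(positives)]
    decoy_scores = table[method].to_numpy()[len(positives):]
    runs: dict[int, EvaluationRun] = {}
    for mult in multipliers:
        k = mult * len(positives)
        scores = np.concatenate([pos_scores, decoy_scores[:k]])
        labels = np.concatenate([np.ones(len(positives), int), np.zeros(k, int)])
        runs[mult] = roc_pr(scores, labels, method=method, ratio=float(mult))
    return runs
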