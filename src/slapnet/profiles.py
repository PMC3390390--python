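"""Polypharmacology profiles and drug-similarity networks.

A drug's vector of association scores across a panel of targets is a
biological signature: drugs acting through the same targets (or the same
neighborhoods) have correlated signatures even when their structures
differ. This module builds drug x target score matrices, filters out rows
and columns with no significant association (so every retained drug has at
least one valid target and vice versa), measures profile similarity with
the Pearson correlation coefficient, and exports thresholded similarity
networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SlapError
from .graph import SemanticGraph
from .scoring import (
    NullModel,
    PatternStats,
    association_score,
    p_value,
    significance_threshold,
)

__all__ = [
    "ScoreMatrix",
    "build_score_matrix",
    "filter_matrix",
    "profile_similarity",
    "build_similarity_network",
    "query_similar",
    "write_matrix_tsv",
    "write_matrix_long_tsv",
    "write_network",
]


@dataclass
class ScoreMatrix:
    """Drugs x targets association scores with per-cell status.

    ``scores`` holds nonnegative association scores; ``status`` holds one
    of ``scored`` / ``no_paths`` / ``not_mapped`` per cell (unmapped drugs
    yield whole rows of zeros flagged ``not_mapped``).
    """

    scores: pd.DataFrame
    status: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.scores.index.equals(self.status.index) or not self.scores.columns.equals(
            self.status.columns
        ):
            raise ValueError("scores and status must share index and columns")

    @property
    def drugs(self) -> list[str]:
        return list(self.scores.index)

    @property
    def targets(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape


def build_score_matrix(
    drugs: Sequence[str],
    targets: Sequence[str],
    graph: SemanticGraph,
    stats: PatternStats,
    informative: set[str] | None = None,
    exclude_direct: bool = False,
    max_length: int = 3,
) -> ScoreMatrix:
    """Full association-score matrix of every drug against every target."""
    if not drugs or not targets:
        raise ValueError("drug and target lists must be non-empty")
    drugs, targets = list(dict.fromkeys(drugs)), list(dict.fromkeys(targets))
    score_rows, status_rows = [], []
    for drug in drugs:
        srow, trow = [], []
        for target in targets:
            res = association_score(
                drug,
                target,
                graph,
                stats,
                informative=informative,
                exclude_direct=exclude_direct,
                max_length=max_length,
            )
            srow.append(res.association_score)
            trow.append(res.status)
        score_rows.append(srow)
        status_rows.append(trow)
    return ScoreMatrix(
        scores=pd.DataFrame(score_rows, index=drugs, columns=targets, dtype=float),
        status=pd.DataFrame(status_rows, index=drugs, columns=targets),
    )


def filter_matrix(
    matrix: ScoreMatrix,
    null: NullModel,
    alpha: float = 0.05,
    mode: str = "columns",
) -> ScoreMatrix:
    """Drop rows / columns whose maximum score is not significant.

    The cut-off is the association score with null p-value ``alpha``; a
    column (target) survives only if at least one drug scores >= the
    cut-off, and symmetrically for rows, so every retained protein is a
    target of at least one drug. Idempotent, never grows the matrix.
    """
    if mode not in ("rows", "columns", "both"):
        raise ValueError("mode must be 'rows', 'columns' or 'both'")
    cutoff = significance_threshold(null, alpha)
    scores, status = matrix.scores, matrix.status
    if mode in ("rows", "both"):
        keep = scores.max(axis=1) >= cutoff
        scores, status = scores.loc[keep], status.loc[keep]
    if mode in ("columns", "both"):
        keep = scores.max(axis=0) >= cutoff
        scores, status = scores.loc[:, keep], status.loc[:, keep]
    if scores.empty:
        raise SlapError(
            f"significance filtering at alpha={alpha} (score cut-off {cutoff:.3g}) "
            f"removed every row/column of the {matrix.shape} matrix"
        )
    return ScoreMatrix(scores=scores.copy(), status=status.copy())


def profile_similarity(matrix: ScoreMatrix) -> pd.DataFrame:
    """Pearson correlation between every unordered pair of drug profiles.

    Symmetric with unit diagonal. A zero-variance profile (a drug with a
    flat score vector) has undefined correlations, reported as missing
    (NaN) rather than zero.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 drugs and 2 targets for profile similarity")
    sim = matrix.scores.T.corr(method="pearson")
    variable = matrix.scores.std(axis=1) > 0
    for drug, ok in variable.items():
        if ok:
            sim.loc[drug, drug] = 1.0
    return sim


def build_similarity_network(
    similarities: pd.DataFrame,
    threshold: float = 0.75,
    annotations: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Threshold the similarity table into a weighted drug network.

    Two drugs are linked iff their Pearson coefficient is >= ``threshold``
    (undefined similarities never link). Every drug remains a node, so
    unclustered drugs stay visible as isolates.
    """
    g = nx.Graph()
    drugs = list(similarities.index)
    for drug in drugs:
        attrs = {"annotation": annotations[drug]} if annotations and drug in annotations else {}
        g.add_node(drug, **attrs)
    for i, u in enumerate(drugs):
        for v in drugs[i + 1:]:
            r = similarities.loc[u, v]
            if pd.notna(r) and r >= threshold:
                g.add_edge(u, v, weight=float(r))
    return g


def query_similar(
    matrix: ScoreMatrix, query_drug: str, top_k: int | None = None
) -> pd.Series:
    """Drugs ranked by descending profile correlation with ``query_drug``.

    The query itself is excluded; ties break by drug id. ``top_k`` larger
    than the library returns the full ranking.
    """
    if query_drug not in matrix.scores.index:
        raise KeyError(f"unknown drug {query_drug!r}")
    sim = profile_similarity(matrix)
    others = sim.loc[query_drug].drop(query_drug)
    ranked = others.sort_index().sort_values(ascending=False, kind="stable")
    if top_k is not None:
        ranked = ranked.iloc[:top_k]
    return ranked


# -- exports -------------------------------------------------------------


def write_matrix_tsv(matrix: ScoreMatrix, path: str | Path) -> None:
    """Wide-form TSV: one row per drug, one column per target."""
    matrix.scores.to_csv(path, sep="\t", index_label="drug")


def write_matrix_long_tsv(
    matrix: ScoreMatrix, path: str | Path, null: NullModel | None = None
) -> None:
    """Long-form TSV: drug, target, score, p_value, status."""
    long = matrix.scores.stack().rename("score").reset_index()
    long.columns = ["drug", "target", "score"]
    long["p_value"] = (
        [p_value(s, null) for s in long["score"]] if null is not None else np.nan
    )
    long["status"] = matrix.status.stack().reset_index(drop=True)
    long.to_csv(path, sep="\t", index=False)


def write_network(
    network: nx.Graph, edgelist_path: str | Path, graphml_path: str | Path | None = None
) -> None:
    """Write a similarity network as weighted edge-list TSV (and GraphML)."""
    with Path(edgelist_path).open("w", encoding="utf-8") as fh:
        fh.write("drug_a\tdrug_b\tweight\n")
        for u, v, data in sorted(network.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['weight']:.6f}\n")
    if graphml_path is not None:
        nx.write_graphml(network, graphml_path)
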