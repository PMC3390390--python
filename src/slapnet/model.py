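"""Model facade: fit the full association model on a network and score with it.

:class:`SlapModel` is constructed from a :class:`~slapnet.graph.SemanticGraph`
plus the drug / target pools; :meth:`SlapModel.fit` runs the three fitting
stages —

1. per-pattern raw-score normals from a seeded random-pair sample,
2. optional pattern-informativeness selection against one or more
   (positives, decoys) benchmarks,
3. the log-normal null over random-pair association scores —

and returns a :class:`SlapResults` carrying the fitted pattern statistics,
the informative-pattern set, the null model and provenance. Results score
pairs, attach p-values, build score matrices, summarize as a table, and
round-trip losslessly through a versioned JSON bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluate, profiles
from .errors import SlapError
from .graph import SemanticGraph
from .patterns import PatternReport, evaluate_patterns
from .scoring import (
    MIN_PATTERN_PATHS,
    NullModel,
    PatternStats,
    association_score,
    fit_null_model,
    fit_pattern_stats,
    p_value,
    sample_pairs,
    significance_threshold,
)

__all__ = ["SlapModel", "SlapResults"]

BUNDLE_FORMAT_VERSION = 1

Pair = tuple[str, str]


class SlapModel:
    """Association model over a typed heterogeneous network.

    Parameters
    ----------
    graph
        The network to model.
    drugs, targets
        Source and target pools used for random-pair sampling and as the
        default panels. Default: all ``Compound`` / all ``Target`` nodes.
    known_positives
        Known interacting pairs; excluded from every random-pair sample so
        the "random" background is not contaminated by true links.
    max_path_length
        Path length bound for every enumeration (default 3 edges).
    """

    def __init__(
        self,
        graph: SemanticGraph,
        drugs: Sequence[str] | None = None,
        targets: Sequence[str] | None = None,
        known_positives: Sequence[Pair] | None = None,
        max_path_length: int = 3,
    ):
        self.graph = graph
        self.drugs = list(drugs) if drugs is not None else graph.nodes("Compound")
        self.targets = list(targets) if targets is not None else graph.nodes("Target")
        if not self.drugs or not self.targets:
            raise ValueError("drug and target pools must be non-empty")
        self.known_positives = set(known_positives or ())
        self.max_path_length = int(max_path_length)

    def fit(
        self,
        seed: int,
        n_sample_pairs: int = 2000,
        n_null_pairs: int = 1000,
        benchmarks: Sequence[tuple[Sequence[Pair], Sequence[Pair]]] | None = None,
        pattern_threshold: float = 0.55,
        min_pattern_paths: int = MIN_PATTERN_PATHS,
    ) -> "SlapResults":
        """Fit pattern statistics, pattern selection and the null model.

        ``benchmarks`` is an optional list of (positives, decoys) pair-list
        tuples for pattern selection; without it every usable pattern is
        informative. Fully deterministic given the seed.
        """
        ss = np.random.SeedSequence(seed)
        rng_stats, rng_null = (np.random.default_rng(s) for s in ss.spawn(2))

        stats = fit_pattern_stats(
            self.graph,
            self.drugs,
            self.targets,
            n_pairs=n_sample_pairs,
            seed=rng_stats,
            max_length=self.max_path_length,
            exclude_pairs=self.known_positives,
            min_paths=min_pattern_paths,
        )

        reports: dict[str, PatternReport] = {}
        if benchmarks:
            reports = evaluate_patterns(
                stats.usable_signatures(),
                benchmarks,
                self.graph,
                threshold=pattern_threshold,
                max_length=self.max_path_length,
            )
            informative = {s for s, r in reports.items() if r.informative}
        else:
            informative = stats.usable_signatures()

        null_pairs = sample_pairs(
            self.drugs,
            self.targets,
            n_null_pairs,
            rng_null,
            exclude=self.known_positives,
        )
        null_scores = [
            association_score(
                s, t, self.graph, stats, informative, max_length=self.max_path_length
            ).association_score
            for s, t in null_pairs
        ]
        null = fit_null_model(null_scores)

        return SlapResults(
            graph=self.graph,
            pattern_stats=stats,
            informative=informative,
            null=null,
            pattern_reports=reports,
            max_path_length=self.max_path_length,
            provenance={
                "seed": int(seed),
                "n_sample_pairs": int(n_sample_pairs),
                "n_null_pairs": int(n_null_pairs),
                "pattern_threshold": float(pattern_threshold),
                "n_benchmarks": len(benchmarks or ()),
                "n_drugs": len(self.drugs),
                "n_targets": len(self.targets),
            },
        )


@dataclass
class SlapResults:
    """Fitted association model: pattern normals, informative set, null.

    The graph is carried by reference for scoring; the statistical state
    (everything except the graph) serializes to a versioned JSON bundle.
    """

    graph: SemanticGraph | None
    pattern_stats: PatternStats
    informative: set[str]
    null: NullModel
    pattern_reports: Mapping[str, PatternReport] = field(default_factory=dict)
    max_path_length: int = 3
    provenance: dict = field(default_factory=dict)

    # -- scoring -------------------------------------------------------

    def _require_graph(self) -> SemanticGraph:
        if self.graph is None:
            raise SlapError("results were loaded without a graph; attach one via .graph")
        return self.graph

    def score_pair(self, source: str, target: str, exclude_direct: bool = False):
        """Full :class:`~slapnet.scoring.AssociationResult` for one pair."""
        return association_score(
            source,
            target,
            self._require_graph(),
            self.pattern_stats,
            informative=self.informative,
            exclude_direct=exclude_direct,
            max_length=self.max_path_length,
            null=self.null,
        )

    def score_pairs(self, pairs: Sequence[Pair], exclude_direct: bool = True) -> pd.DataFrame:
        return evaluate.score_pairs(
            pairs,
            self._require_graph(),
            self.pattern_stats,
            informative=self.informative,
            exclude_direct=exclude_direct,
            max_length=self.max_path_length,
            null=self.null,
        )

    def score_matrix(
        self,
        drugs: Sequence[str],
        targets: Sequence[str],
        exclude_direct: bool = False,
    ) -> profiles.ScoreMatrix:
        return profiles.build_score_matrix(
            drugs,
            targets,
            self._require_graph(),
            self.pattern_stats,
            informative=self.informative,
            exclude_direct=exclude_direct,
            max_length=self.max_path_length,
        )

    def p_value(self, score: float) -> float:
        return p_value(score, self.null)

    def significance_threshold(self, alpha: float = 0.05) -> float:
        return significance_threshold(self.null, alpha)

    # -- reporting -----------------------------------------------------

    def pattern_table(self) -> pd.DataFrame:
        """Per-pattern fit and selection summary as a DataFrame."""
        rows = []
        for sig in self.pattern_stats:
            st = self.pattern_stats.get(sig)
            row = {
                "pattern": sig,
                "n_paths": st.n,
                "mu": st.mu,
                "sigma": st.sigma,
                "usable": st.usable,
                "informative": sig in self.informative,
            }
            report = self.pattern_reports.get(sig)
            if report is not None:
                for i, a in enumerate(report.aurocs):
                    row[f"auroc_{i + 1}"] = a
            rows.append(row)
        return pd.DataFrame(rows).set_index("pattern").sort_index()

    def summary(self) -> str:
        """Human-readable fit summary."""
        table = self.pattern_table()
        lines = [
            "Semantic link association model",
            "=" * 64,
            f"patterns fitted:      {len(self.pattern_stats)}",
            f"usable patterns:      {len(self.pattern_stats.usable_signatures())}",
            f"informative patterns: {len(self.informative)}",
            f"max path length:      {self.max_path_length}",
            (
                f"null model:           log-normal(mu={self.null.mu_log:.4f}, "
                f"sigma={self.null.sigma_log:.4f}), n={self.null.n} "
                f"(+{self.null.n_zero} zero-score pairs excluded)"
            ),
            f"score at p=0.05:      {self.significance_threshold(0.05):.4f}",
            "",
            table.to_string(max_colwidth=60, float_format=lambda x: f"{x:.4f}"),
        ]
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize the fitted state (not the graph) as a JSON bundle."""
        payload = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "max_path_length": self.max_path_length,
            "pattern_stats": self.pattern_stats.to_dict(),
            "informative": sorted(self.informative),
            "null": self.null.to_dict(),
            "pattern_reports": {
                s: {"aurocs": list(r.aurocs), "informative": r.informative}
                for s, r in sorted(self.pattern_reports.items())
            },
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path, graph: SemanticGraph | None = None) -> "SlapResults":
        try:
            payload = json.loads(Path(path).read_text(encoding="utf-8"))
            version = payload["format_version"]
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise SlapError(f"corrupt model bundle {path}: {exc}") from exc
        if version != BUNDLE_FORMAT_VERSION:
            raise SlapError(
                f"model bundle {path} has format version {version}, "
                f"expected {BUNDLE_FORMAT_VERSION}"
            )
        return cls(
            graph=graph,
            pattern_stats=PatternStats.from_dict(payload["pattern_stats"]),
            informative=set(payload["informative"]),
            null=NullModel.from_dict(payload["null"]),
            pattern_reports={
                s: PatternReport(s, tuple(r["aurocs"]), bool(r["informative"]))
                for s, r in payload.get("pattern_reports", {}).items()
            },
            max_path_length=int(payload["max_path_length"]),
            provenance=payload.get("provenance", {}),
        )
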