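"""Statistical core: raw path scores, pattern z-normalization, association
scores, and the random-pair null model.

The traversal model assigns each step from node ``v`` along an edge of
type ``t`` the probability ``1 / type_degree(v, t)`` — equal probability
over same-type neighbors. A path's log-probability is the sum of step
log-probabilities; because the graph is undirected, the *raw score* of a
path is the average of the two traversal directions' log-probabilities
(natural log; any base only rescales raw scores within a pattern by a
constant and leaves every z score unchanged).

Raw scores are comparable only within a semantic pattern, so each pattern
is normalized against a random-pair sample: raw scores of paths collected
from randomly sampled (source, target) pairs are fitted per pattern to a
normal distribution, and each observed path is converted to the z score
``(raw - mu) / sigma`` of its pattern. Paths with z > 0 in informative
patterns are *valid*, and the association score of a pair is the sum of
its valid-path z scores (zero if none).

Finally, the association scores of random pairs are themselves summarized
by a log-normal null: the natural logs of strictly positive random-pair
scores are fitted to a normal, giving upper-tail p-values and
significance thresholds for observed scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .errors import DegenerateFitError, NotMappedError, SlapError
from .graph import SemanticGraph
from .paths import Path, enumerate_paths, pattern_signature

__all__ = [
    "raw_path_score",
    "PatternStat",
    "PatternStats",
    "sample_pairs",
    "fit_pattern_stats",
    "path_z_score",
    "PathScore",
    "AssociationResult",
    "score_paths",
    "association_score",
    "NullModel",
    "fit_null_model",
    "p_value",
    "significance_threshold",
]

#: usability gates for a fitted pattern
MIN_PATTERN_PATHS = 30
MIN_PATTERN_SIGMA = 1e-9


def raw_path_score(path: Path, graph: SemanticGraph, log_base: float | None = None) -> float:
    """Average of the two directional traversal log-probabilities of a path.

    Each step from node ``v`` over an edge of type ``t`` contributes
    ``log(1 / type_degree(v, t))``; the forward (source->target) and
    backward (target->source) sums are averaged. Always <= 0, and equal to
    0 only when every step in both directions has type degree 1.

    ``log_base`` defaults to the natural log. (Changing it rescales all
    raw scores by one constant, so pattern z scores are base-invariant.)
    """
    forward = 0.0
    backward = 0.0
    for u, etype, v in path.steps():
        deg_u = graph.type_degree(u, etype)
        deg_v = graph.type_degree(v, etype)
        if deg_u == 0 or deg_v == 0:
            raise SlapError(
                f"internal inconsistency: step {u!r}-{etype}-{v!r} has a zero type degree"
            )
        forward -= math.log(deg_u)
        backward -= math.log(deg_v)
    raw = 0.5 * (forward + backward)
    if log_base is not None:
        raw /= math.log(log_base)
    return raw


@dataclass(frozen=True)
class PatternStat:
    """Fitted normal of one pattern's random-pair raw scores."""

    signature: str
    mu: float
    sigma: float
    n: int
    usable: bool


class PatternStats:
    """Collection of per-pattern fitted normals keyed by signature.

    A pattern is *usable* when it was seen on at least ``min_paths``
    sampled paths and its raw-score standard deviation exceeds
    ``min_sigma``; unusable patterns contribute no z scores.
    """

    def __init__(self, stats: Mapping[str, PatternStat]):
        self._stats = dict(stats)

    def __len__(self) -> int:
        return len(self._stats)

    def __iter__(self):
        return iter(sorted(self._stats))

    def __contains__(self, signature: str) -> bool:
        return signature in self._stats

    def get(self, signature: str) -> PatternStat | None:
        return self._stats.get(signature)

    def usable_signatures(self) -> set[str]:
        return {s for s, st in self._stats.items() if st.usable}

    def to_dict(self) -> dict:
        return {
            s: {"mu": st.mu, "sigma": st.sigma, "n": st.n, "usable": st.usable}
            for s, st in sorted(self._stats.items())
        }

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PatternStats":
        return cls(
            {
                s: PatternStat(
                    signature=s,
                    mu=float(d["mu"]),
                    sigma=float(d["sigma"]),
                    n=int(d["n"]),
                    usable=bool(d["usable"]),
                )
                for s, d in raw.items()
            }
        )

    @classmethod
    def from_scores(
        cls,
        scores_by_pattern: Mapping[str, Sequence[float]],
        min_paths: int = MIN_PATTERN_PATHS,
        min_sigma: float = MIN_PATTERN_SIGMA,
    ) -> "PatternStats":
        """Fit per-pattern normals (sample mean / sd) from raw-score pools."""
        stats = {}
        for sig, scores in scores_by_pattern.items():
            arr = np.asarray(scores, dtype=float)
            n = arr.size
            mu = float(arr.mean()) if n else float("nan")
            sigma = float(arr.std(ddof=1)) if n > 1 else 0.0
            stats[sig] = PatternStat(
                signature=sig,
                mu=mu,
                sigma=sigma,
                n=n,
                usable=(n >= min_paths and sigma > min_sigma),
            )
        return cls(stats)


def sample_pairs(
    sources: Sequence[str],
    targets: Sequence[str],
    n_pairs: int,
    rng: np.random.Generator,
    exclude: Iterable[tuple[str, str]] | None = None,
) -> list[tuple[str, str]]:
    """Sample ``n_pairs`` distinct (source, target) pairs uniformly without
    replacement from the cross product, skipping ``exclude`` (e.g. known
    positive pairs so the sample represents the random background)."""
    sources = sorted(set(sources))
    targets = sorted(set(targets))
    if not sources or not targets:
        raise ValueError("source and target pools must be non-empty")
    excluded = set(exclude or ())
    total = len(sources) * len(targets)
    if total > 50_000_000:
        raise ValueError("cross product too large to sample without replacement")
    if n_pairs > total - len(excluded):
        raise ValueError(
            f"cannot sample {n_pairs} pairs from a pool of {total - len(excluded)}"
        )
    perm = rng.permutation(total)
    out: list[tuple[str, str]] = []
    nt = len(targets)
    for idx in perm:
        pair = (sources[idx // nt], targets[idx % nt])
        if pair in excluded:
            continue
        out.append(pair)
        if len(out) == n_pairs:
            break
    return out


def fit_pattern_stats(
    graph: SemanticGraph,
    source_pool: Sequence[str],
    target_pool: Sequence[str],
    n_pairs: int,
    seed: int | np.random.Generator,
    max_length: int = 3,
    exclude_pairs: Iterable[tuple[str, str]] | None = None,
    min_paths: int = MIN_PATTERN_PATHS,
    min_sigma: float = MIN_PATTERN_SIGMA,
    log_base: float | None = None,
    return_raw: bool = False,
):
    """Fit per-pattern raw-score normals from a random-pair sample.

    Samples ``n_pairs`` (source, target) pairs uniformly without
    replacement (seeded, hence fully reproducible), enumerates all paths
    of length <= ``max_length`` for each, and fits each pattern's mean and
    standard deviation over the pooled raw scores.

    Returns ``PatternStats``, or ``(PatternStats, raw_scores_by_pattern)``
    when ``return_raw`` is true.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = sample_pairs(source_pool, target_pool, n_pairs, rng, exclude=exclude_pairs)
    scores_by_pattern: dict[str, list[float]] = {}
    for source, target in pairs:
        for path in enumerate_paths(graph, source, target, max_length=max_length):
            sig = pattern_signature(path, graph)
            scores_by_pattern.setdefault(sig, []).append(
                raw_path_score(path, graph, log_base=log_base)
            )
    stats = PatternStats.from_scores(scores_by_pattern, min_paths=min_paths, min_sigma=min_sigma)
    if return_raw:
        return stats, {s: np.asarray(v) for s, v in scores_by_pattern.items()}
    return stats


def path_z_score(raw: float, stat: PatternStat) -> float:
    """z = (raw - mu) / sigma of the path's pattern; requires a usable pattern."""
    if not stat.usable:
        raise DegenerateFitError(
            f"pattern {stat.signature!r} is unusable (n={stat.n}, sigma={stat.sigma})"
        )
    return (raw - stat.mu) / stat.sigma


@dataclass(frozen=True)
class PathScore:
    """One enumerated path with its raw score, z score and validity."""

    path: Path
    raw: float
    z: float | None  # None when the pattern is unusable
    signature: str
    valid: bool


@dataclass
class AssociationResult:
    """Association between a (source, target) pair.

    ``status`` is one of ``scored`` (paths found and scored), ``no_paths``
    (both nodes mapped but unconnected within the length bound) and
    ``not_mapped`` (at least one node absent from the network). The
    association score is the sum of valid-path z scores; a p-value is
    attached only when the pair was scored and a null model was supplied.
    """

    source: str
    target: str
    status: str
    paths: list[PathScore] = field(default_factory=list)
    association_score: float = 0.0
    p_value: float | None = None


def score_paths(
    paths: Sequence[Path],
    graph: SemanticGraph,
    stats: PatternStats,
    informative: set[str] | None = None,
) -> tuple[float, list[PathScore]]:
    """Score enumerated paths; returns (association score, per-path records).

    A path is valid — contributes its z score to the sum — iff its pattern
    is usable, its z score is strictly positive, and its pattern is in the
    informative set (every usable pattern, when ``informative`` is None).
    """
    records: list[PathScore] = []
    total = 0.0
    for path in paths:
        sig = pattern_signature(path, graph)
        raw = raw_path_score(path, graph)
        stat = stats.get(sig)
        if stat is None or not stat.usable:
            records.append(PathScore(path, raw, None, sig, False))
            continue
        z = path_z_score(raw, stat)
        valid = z > 0 and (informative is None or sig in informative)
        if valid:
            total += z
        records.append(PathScore(path, raw, z, sig, valid))
    return total, records


def association_score(
    source: str,
    target: str,
    graph: SemanticGraph,
    stats: PatternStats,
    informative: set[str] | None = None,
    exclude_direct: bool = False,
    max_length: int = 3,
    null: "NullModel | None" = None,
) -> AssociationResult:
    """Association score (and optional p-value) of one node pair.

    With ``exclude_direct`` the direct edges between the pair are removed
    from path enumeration, so longer paths re-using a direct edge are also
    excluded and the score reflects neighborhood evidence only ("missing
    link" setting). Unmapped nodes yield status ``not_mapped`` rather than
    an exception.
    """
    excluded = graph.direct_edges(source, target) if exclude_direct else None
    try:
        paths = enumerate_paths(
            graph, source, target, max_length=max_length, excluded_edges=excluded
        )
    except NotMappedError:
        return AssociationResult(source, target, status="not_mapped")
    if not paths:
        return AssociationResult(source, target, status="no_paths")
    score, records = score_paths(paths, graph, stats, informative)
    result = AssociationResult(
        source, target, status="scored", paths=records, association_score=score
    )
    if null is not None:
        result.p_value = p_value(score, null)
    return result


@dataclass(frozen=True)
class NullModel:
    """Normal fit of the natural-log association scores of random pairs."""

    mu_log: float
    sigma_log: float
    n: int  # random pairs with a strictly positive score
    n_zero: int  # zero-score pairs excluded from the fit

    def to_dict(self) -> dict:
        return {
            "mu_log": self.mu_log,
            "sigma_log": self.sigma_log,
            "n": self.n,
            "n_zero": self.n_zero,
        }

    @classmethod
    def from_dict(cls, raw: Mapping) -> "NullModel":
        return cls(
            mu_log=float(raw["mu_log"]),
            sigma_log=float(raw["sigma_log"]),
            n=int(raw["n"]),
            n_zero=int(raw["n_zero"]),
        )


def fit_null_model(scores: Iterable[float], min_n: int = 30) -> NullModel:
    """Fit the log-normal null from random-pair association scores.

    Zero (and negative, which cannot occur) scores are excluded — their
    log is undefined — and their count is reported on the model. Requires
    at least ``min_n`` strictly positive scores with nonzero spread.
    """
    arr = np.asarray(list(scores), dtype=float)
    positive = arr[arr > 0]
    n_zero = int(arr.size - positive.size)
    if positive.size == 0:
        raise DegenerateFitError("all association scores are zero; null model undefined")
    if positive.size < min_n:
        raise DegenerateFitError(
            f"need >= {min_n} strictly positive scores to fit the null, got {positive.size}"
        )
    logs = np.log(positive)
    sigma = float(logs.std(ddof=1))
    if sigma <= 0:
        raise DegenerateFitError("degenerate null fit: log scores have zero spread")
    return NullModel(mu_log=float(logs.mean()), sigma_log=sigma, n=int(positive.size), n_zero=n_zero)


def p_value(score: float, null: NullModel) -> float:
    """Upper-tail probability of log(score) under the fitted null.

    Strictly decreasing in the score. A score <= 0 (no valid path) is
    assigned p = 1 by convention: no evidence of association.
    """
    if score <= 0:
        return 1.0
    return float(norm.sf(math.log(score), loc=null.mu_log, scale=null.sigma_log))


def significance_threshold(null: NullModel, alpha: float) -> float:
    """The association score whose null p-value equals ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(math.exp(norm.isf(alpha, loc=null.mu_log, scale=null.sigma_log)))
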