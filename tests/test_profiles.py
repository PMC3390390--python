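import numpy as np
import networkx as nx
import pandas as pd
import pytest

from slapnet import profiles as prof
from slapnet.errors import SlapError
from slapnet.scoring import NullModel, association_score


def make_matrix(scores: np.ndarray, drugs=None, targets=None) -> prof.ScoreMatrix:
    drugs = drugs or [f"d{i}" for i in range(scores.shape[0])]
    targets = targets or [f"t{j}" for j in range(scores.shape[1])]
    frame = pd.DataFrame(scores, index=drugs, columns=targets, dtype=float)
    status = pd.DataFrame("scored", index=drugs, columns=targets)
    return prof.ScoreMatrix(scores=frame, status=status)


NULL = NullModel(mu_log=0.0, sigma_log=1.0, n=1000, n_zero=0)
# score cut-off at alpha=0.05 is exp(1.6449) ~ 5.18


def test_build_score_matrix_consistent_with_single_calls(bundle0, fitted0):
    drugs = bundle0.compounds[:3] + ["unmapped_drug"]
    targets = bundle0.targets[:4]
    matrix = fitted0.score_matrix(drugs, targets)
    assert matrix.shape == (4, 4)
    for d in drugs[:3]:
        for t in targets:
            res = association_score(
                d, t, bundle0.graph, fitted0.pattern_stats, fitted0.informative
            )
            assert matrix.scores.loc[d, t] == pytest.approx(res.association_score)
            assert matrix.status.loc[d, t] == res.status
    assert (matrix.scores.loc["unmapped_drug"] == 0).all()
    assert (matrix.status.loc["unmapped_drug"] == "not_mapped").all()
    with pytest.raises(ValueError):
        fitted0.score_matrix([], targets)


def test_filter_matrix_modes_and_idempotence():
    scores = np.array([
        [9.0, 0.1, 0.2],   # strong row
        [6.0, 0.3, 0.1],   # passes via column 0
        [0.2, 0.1, 0.3],   # weak row, dropped in rows/both modes
    ])
    matrix = make_matrix(scores)
    cols = prof.filter_matrix(matrix, NULL, alpha=0.05, mode="columns")
    assert cols.targets == ["t0"]  # only column 0 has a significant hit
    assert cols.drugs == ["d0", "d1", "d2"]
    both = prof.filter_matrix(matrix, NULL, alpha=0.05, mode="both")
    assert both.drugs == ["d0", "d1"] and both.targets == ["t0"]
    again = prof.filter_matrix(both, NULL, alpha=0.05, mode="both")
    assert again.scores.equals(both.scores)  # idempotent
    with pytest.raises(SlapError, match="removed every"):
        prof.filter_matrix(make_matrix(np.full((2, 2), 0.1)), NULL, alpha=0.05)
    with pytest.raises(ValueError):
        prof.filter_matrix(matrix, NULL, mode="diagonal")


def test_profile_similarity_basic_geometry():
    base = np.array([1.0, 4.0, 2.0, 7.0])
    scores = np.vstack([base, base, 10 - base, np.full(4, 3.0)])
    sim = prof.profile_similarity(make_matrix(scores))
    assert sim.loc["d0", "d1"] == pytest.approx(1.0)
    assert sim.loc["d0", "d2"] == pytest.approx(-1.0)
    assert np.isnan(sim.loc["d0", "d3"])  # zero-variance profile: missing, not 0
    assert sim.loc["d0", "d0"] == 1.0
    finite = sim.to_numpy()[np.isfinite(sim.to_numpy())]
    assert ((finite >= -1 - 1e-12) & (finite <= 1 + 1e-12)).all()
    assert np.allclose(sim.to_numpy(), sim.to_numpy().T, equal_nan=True)


def test_profile_similarity_matches_two_pass_covariance():
    rng = np.random.default_rng(8)
    scores = rng.gamma(2.0, 2.0, size=(6, 9))
    sim = prof.profile_similarity(make_matrix(scores))
    for i in range(6):
        for j in range(6):
            a, b = scores[i], scores[j]
            cov = ((a - a.mean()) * (b - b.mean())).sum() / (len(a) - 1)
            r = cov / (a.std(ddof=1) * b.std(ddof=1))
            assert sim.iloc[i, j] == pytest.approx(r, abs=1e-12)


def test_similarity_network_thresholding():
    scores = np.vstack([[1, 2, 3, 4], [1, 2, 3, 4.5], [4, 3, 2, 1]]).astype(float)
    sim = prof.profile_similarity(make_matrix(scores))
    empty = prof.build_similarity_network(sim, threshold=1.1)
    assert empty.number_of_edges() == 0
    assert empty.number_of_nodes() == 3  # isolates retained
    complete = prof.build_similarity_network(sim, threshold=-1.0)
    assert complete.number_of_edges() == 3
    assert not any(u == v for u, v in complete.edges())
    mid = prof.build_similarity_network(sim, threshold=0.75, annotations={"d0": "groupA"})
    assert mid.has_edge("d0", "d1") and not mid.has_edge("d0", "d2")
    assert mid.nodes["d0"]["annotation"] == "groupA"
    assert all(w >= 0.75 for _, _, w in mid.edges(data="weight"))


def test_query_similar_ranking():
    base = np.array([1.0, 5.0, 2.0, 8.0, 3.0])
    rng = np.random.default_rng(1)
    scores = np.vstack([base, base, base + rng.normal(0, 1.5, 5), rng.normal(3, 2, 5)])
    matrix = make_matrix(scores, drugs=["query", "twin", "near", "far"])
    ranked = prof.query_similar(matrix, "query")
    assert list(ranked.index)[0] == "twin"
    assert ranked.iloc[0] == pytest.approx(1.0)
    assert "query" not in ranked.index
    assert len(prof.query_similar(matrix, "query", top_k=100)) == 3
    # ranking invariant under row permutation
    perm = make_matrix(scores[::-1], drugs=["far", "near", "twin", "query"])
    assert list(prof.query_similar(perm, "query").index) == list(ranked.index)
    with pytest.raises(KeyError):
        prof.query_similar(matrix, "ghost")


def test_profile_and_structural_similarity_are_distinct_signals(schema):
    # two drugs with identical substructure wiring but disjoint binding
    # neighborhoods: structurally alike, biologically different.
    from slapnet.graph import SemanticGraph
    from slapnet.scoring import PatternStat, PatternStats

    g = SemanticGraph(schema=schema)
    for i in range(4):
        g.add_node(f"T{i}", "Target")
    for n in ("levo", "methyl", "other"):
        g.add_node(n, "Compound")
    for s in ("S1", "S2"):
        g.add_node(s, "Substructure")
        g.add_edge("levo", "hasSubstructure", s)
        g.add_edge("methyl", "hasSubstructure", s)
    g.add_edge("levo", "bind", "T0")
    g.add_edge("levo", "bind", "T1")
    g.add_edge("methyl", "bind", "T2")
    g.add_edge("methyl", "bind", "T3")
    g.add_edge("other", "bind", "T0")
    g.add_edge("other", "bind", "T2")
    sig = "Compound|bind|Target"
    stats = PatternStats({sig: PatternStat(sig, mu=-3.0, sigma=1.0, n=100, usable=True)})
    matrix = prof.build_score_matrix(
        ["levo", "methyl"], [f"T{i}" for i in range(4)], g, stats
    )
    sim = prof.profile_similarity(matrix)
    assert sim.loc["levo", "methyl"] < 0  # anti-correlated target profiles
    assert g.neighbors("levo")["hasSubstructure"] == g.neighbors("methyl")["hasSubstructure"]


def test_matrix_exports_roundtrip(tmp_path, bundle0, fitted0):
    matrix = fitted0.score_matrix(bundle0.compounds[:3], bundle0.targets[:3])
    prof.write_matrix_tsv(matrix, tmp_path / "wide.tsv")
    wide = pd.read_csv(tmp_path / "wide.tsv", sep="\t", index_col="drug")
    assert np.allclose(wide.to_numpy(), matrix.scores.to_numpy())
    prof.write_matrix_long_tsv(matrix, tmp_path / "long.tsv", null=fitted0.null)
    long = pd.read_csv(tmp_path / "long.tsv", sep="\t")
    assert len(long) == 9
    assert {"drug", "target", "score", "p_value", "status"} <= set(long.columns)
    assert ((long["p_value"] > 0) & (long["p_value"] <= 1)).all()

    sim = prof.profile_similarity(matrix)
    net = prof.build_similarity_network(sim, threshold=-1.0)
    prof.write_network(net, tmp_path / "edges.tsv", tmp_path / "net.graphml")
    reread = nx.read_graphml(tmp_path / "net.graphml")
    assert reread.number_of_nodes() == 3
    lines = (tmp_path / "edges.tsv").read_text().splitlines()
    assert lines[0] == "drug_a\tdrug_b\tweight"
    assert len(lines) - 1 == net.number_of_edges()
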