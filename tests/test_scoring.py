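import math

import numpy as np
import pytest

from conftest import free_edge_graph, one_eighth_chain, one_third_chain
from slapnet.errors import DegenerateFitError
from slapnet.graph import SemanticGraph
from slapnet.paths import Path, enumerate_paths, pattern_signature
from slapnet.scoring import (
    NullModel,
    PatternStat,
    PatternStats,
    association_score,
    fit_null_model,
    fit_pattern_stats,
    p_value,
    path_z_score,
    raw_path_score,
    sample_pairs,
    significance_threshold,
)
from slapnet.synth import SynthConfig, generate


# -- raw path score ------------------------------------------------------


def test_free_edge_scores_zero(schema):
    g = free_edge_graph(schema)
    path = Path(("x", "y"), ("bind",))
    assert raw_path_score(path, g) == pytest.approx(0.0, abs=1e-12)


def test_one_third_chain(schema):
    g = one_third_chain(schema)
    path = Path(("x", "a", "y"), ("bind", "bind"))
    assert raw_path_score(path, g) == pytest.approx(math.log(1 / 3), abs=1e-12)


def test_one_eighth_chain(schema):
    g = one_eighth_chain(schema)
    path = Path(("D", "T1", "C", "T2"), ("bind", "bind", "bind"))
    assert raw_path_score(path, g) == pytest.approx(-math.log(8), abs=1e-12)


def test_raw_scores_nonpositive_and_direction_symmetric(bundle0):
    g = bundle0.graph
    rng = np.random.default_rng(4)
    pairs = sample_pairs(bundle0.compounds, bundle0.targets, 40, rng)
    checked = 0
    for s, t in pairs:
        for path in enumerate_paths(g, s, t):
            raw = raw_path_score(path, g)
            assert raw <= 1e-12
            assert raw == pytest.approx(raw_path_score(path.reversed(), g), abs=1e-12)
            checked += 1
    assert checked > 50


def test_log_base_rescales_raw(schema):
    g = one_eighth_chain(schema)
    path = Path(("D", "T1", "C", "T2"), ("bind", "bind", "bind"))
    natural = raw_path_score(path, g)
    base2 = raw_path_score(path, g, log_base=2)
    assert base2 == pytest.approx(natural / math.log(2), abs=1e-12)


# -- pattern statistics and z scores ------------------------------------


def test_path_z_score_linear():
    stat = PatternStat("sig", mu=-5.0, sigma=2.0, n=100, usable=True)
    assert path_z_score(-5.0, stat) == 0.0
    assert path_z_score(-3.0, stat) == 1.0
    assert path_z_score(-9.0, stat) == -2.0


def test_unusable_pattern_rejected():
    stat = PatternStat("sig", mu=-5.0, sigma=0.0, n=5, usable=False)
    with pytest.raises(DegenerateFitError):
        path_z_score(-5.0, stat)


def test_constant_scores_make_pattern_unusable():
    stats = PatternStats.from_scores({"sig": [-2.0] * 100})
    assert stats.get("sig").usable is False
    assert stats.usable_signatures() == set()


def test_pattern_fit_recovers_normal_parameters():
    rng = np.random.default_rng(42)
    stats = PatternStats.from_scores({"sig": rng.normal(-5.0, 1.0, 10000)})
    st = stats.get("sig")
    assert st.mu == pytest.approx(-5.0, abs=0.05)
    assert st.sigma == pytest.approx(1.0, abs=0.05)
    assert st.usable


@pytest.fixture(scope="module")
def small_bundle():
    cfg = SynthConfig(
        seed=2,
        class_sizes={"Compound": 60, "Target": 40, "GOTerm": 20, "Substructure": 15,
                     "Tissue": 8, "Pathway": 10, "SideEffect": 10, "Disease": 5,
                     "ChemicalOntology": 5, "Gene": 8},
        n_planted=0,
    )
    return generate(cfg)


def test_fit_pattern_stats_deterministic(small_bundle):
    g = small_bundle.graph
    kwargs = dict(source_pool=small_bundle.compounds, target_pool=small_bundle.targets,
                  n_pairs=300, max_length=3)
    a = fit_pattern_stats(g, seed=9, **kwargs)
    b = fit_pattern_stats(g, seed=9, **kwargs)
    assert a.to_dict() == b.to_dict()
    c = fit_pattern_stats(g, seed=10, **kwargs)
    assert c.to_dict() != a.to_dict()


def test_fit_pattern_stats_pool_exhaustion(small_bundle):
    with pytest.raises(ValueError, match="sample"):
        fit_pattern_stats(
            small_bundle.graph, ["C0000"], ["T0000"], n_pairs=5, seed=1
        )


def test_z_scores_invariant_to_log_base(small_bundle):
    g = small_bundle.graph
    kwargs = dict(source_pool=small_bundle.compounds, target_pool=small_bundle.targets,
                  n_pairs=400, max_length=3)
    nat = fit_pattern_stats(g, seed=5, **kwargs)
    b2 = fit_pattern_stats(g, seed=5, log_base=2, **kwargs)
    rng = np.random.default_rng(0)
    for s, t in sample_pairs(small_bundle.compounds, small_bundle.targets, 25, rng):
        for path in enumerate_paths(g, s, t):
            sig = pattern_signature(path, g)
            st_nat, st_b2 = nat.get(sig), b2.get(sig)
            if st_nat is None or not st_nat.usable or not st_b2.usable:
                continue
            z_nat = path_z_score(raw_path_score(path, g), st_nat)
            z_b2 = path_z_score(raw_path_score(path, g, log_base=2), st_b2)
            assert z_b2 == pytest.approx(z_nat, abs=1e-9)


# -- association score ---------------------------------------------------


def _three_path_setup(schema):
    """D and T joined by exactly three paths of three distinct patterns."""
    g = SemanticGraph(schema=schema)
    for n, c in [("D", "Compound"), ("T", "Target"), ("T1", "Target")]:
        g.add_node(n, c)
    g.add_edge("D", "bind", "T")
    g.add_edge("D", "express", "T")
    g.add_edge("D", "bind", "T1")
    g.add_edge("T1", "PPI", "T")
    paths = enumerate_paths(g, "D", "T")
    assert len(paths) == 3
    # engineer stats so the three paths get z = 2.0, -1.0, 0.5
    wanted = {
        "Compound|bind|Target": 2.0,
        "Compound|express|Target": -1.0,
        "Compound|bind|Target|PPI|Target": 0.5,
    }
    stats = PatternStats(
        {
            sig: PatternStat(
                sig,
                mu=raw_path_score(p, g) - z,
                sigma=1.0,
                n=100,
                usable=True,
            )
            for p in paths
            for sig, z in [(pattern_signature(p, g), wanted[pattern_signature(p, g)])]
        }
    )
    return g, stats, set(wanted)


def test_association_sums_positive_z_of_informative_patterns(schema):
    g, stats, informative = _three_path_setup(schema)
    res = association_score("D", "T", g, stats, informative)
    assert res.status == "scored"
    assert res.association_score == pytest.approx(2.5)
    assert sum(1 for p in res.paths if p.valid) == 2


def test_association_ignores_removed_pattern(schema):
    g, stats, informative = _three_path_setup(schema)
    informative = informative - {"Compound|bind|Target"}
    res = association_score("D", "T", g, stats, informative)
    assert res.association_score == pytest.approx(0.5)


def test_association_direct_link_exclusion(schema):
    g, stats, informative = _three_path_setup(schema)
    res = association_score("D", "T", g, stats, informative, exclude_direct=True)
    # both direct edges are gone; only the PPI route remains
    assert [p.signature for p in res.paths] == ["Compound|bind|Target|PPI|Target"]
    assert res.association_score == pytest.approx(0.5)


def test_association_no_paths_and_not_mapped(schema):
    g = SemanticGraph(schema=schema)
    g.add_node("D", "Compound")
    g.add_node("T", "Target")
    stats = PatternStats({})
    res = association_score("D", "T", g, stats)
    assert res.status == "no_paths" and res.association_score == 0.0
    res = association_score("D", "ghost", g, stats)
    assert res.status == "not_mapped" and res.p_value is None


# -- null model ----------------------------------------------------------


def test_null_fit_rejects_degenerate_inputs():
    with pytest.raises(DegenerateFitError):
        fit_null_model([math.e] * 100)  # zero spread
    with pytest.raises(DegenerateFitError):
        fit_null_model([0.0] * 50)  # nothing positive
    with pytest.raises(DegenerateFitError):
        fit_null_model([1.0, 2.0, 3.0])  # too few


def test_null_fit_excludes_zeros_and_counts_them():
    rng = np.random.default_rng(7)
    scores = list(np.exp(rng.normal(3.0, 0.5, 10000))) + [0.0] * 500
    null = fit_null_model(scores)
    assert null.n == 10000
    assert null.n_zero == 500
    assert null.mu_log == pytest.approx(3.0, abs=0.02)
    assert null.sigma_log == pytest.approx(0.5, abs=0.02)


def test_p_value_and_threshold_relationships():
    null = NullModel(mu_log=3.0, sigma_log=0.5, n=1000, n_zero=0)
    assert p_value(math.exp(3.0), null) == pytest.approx(0.5, abs=1e-12)
    assert p_value(math.exp(3.0 + 1.6449 * 0.5), null) == pytest.approx(0.05, abs=1e-4)
    assert p_value(0.0, null) == 1.0
    assert p_value(-1.0, null) == 1.0
    # strictly decreasing in the score
    scores = np.exp(np.linspace(1.0, 6.0, 40))
    pvals = [p_value(s, null) for s in scores]
    assert all(a > b for a, b in zip(pvals, pvals[1:]))
    # threshold round-trip and monotonicity
    for alpha in (0.01, 0.05, 0.1, 0.5):
        thr = significance_threshold(null, alpha)
        assert p_value(thr, null) == pytest.approx(alpha, abs=1e-9)
    assert significance_threshold(null, 0.5) == pytest.approx(math.exp(3.0), abs=1e-9)
    thresholds = [significance_threshold(null, a) for a in (0.01, 0.05, 0.1, 0.5, 0.9)]
    assert all(a > b for a, b in zip(thresholds, thresholds[1:]))
    with pytest.raises(ValueError):
        significance_threshold(null, 1.5)


# -- pair sampling -------------------------------------------------------


def test_sample_pairs_unique_and_excluding():
    rng = np.random.default_rng(0)
    sources = [f"s{i}" for i in range(10)]
    targets = [f"t{i}" for i in range(10)]
    exclude = {("s0", "t0"), ("s1", "t1")}
    pairs = sample_pairs(sources, targets, 98, rng, exclude=exclude)
    assert len(pairs) == len(set(pairs)) == 98
    assert not exclude & set(pairs)
    with pytest.raises(ValueError):
        sample_pairs(sources, targets, 99, rng, exclude=exclude)
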