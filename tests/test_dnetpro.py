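"""Couple scoring, network construction, signature procedures, export."""

import numpy as np
import networkx as nx
import pytest

from radsignet import (CoupleScore, DNetProConfig, build_network,
                       evaluate_signature, export_signature, procedure_a,
                       procedure_b, score_couples)
from radsignet.dnetpro import PartitionError, TooManyFeaturesError
from radsignet.experiments import naive_components, naive_couple_scores


def _planted_data(rng, n=80, p=6, d=3.0, k=2):
    X = rng.normal(size=(n, p))
    y = np.tile([0, 1], n // 2)
    X[:, :k] += d * y[:, None]
    return X, y


def test_four_features_give_six_couples(rng):
    X, y = _planted_data(rng, p=4)
    assert len(score_couples(X, y, inner_folds=3, seed=0)) == 6


def test_couple_scoring_deterministic(rng):
    X, y = _planted_data(rng)
    a = score_couples(X, y, inner_folds=3, seed=4)
    b = score_couples(X, y, inner_folds=3, seed=4)
    assert a == b


def test_couple_scoring_matches_naive_double_loop(rng):
    """Production path and the literal per-pair oracle agree exactly
    (same folds, same classifier settings)."""
    X, y = _planted_data(rng, n=48, p=8, d=1.0)
    ours = {(c.i, c.j): c.score for c in score_couples(X, y, inner_folds=3, seed=2)}
    oracle = naive_couple_scores(X, y, inner_folds=3, seed=2)
    assert ours.keys() == oracle.keys()
    for key in oracle:
        assert ours[key] == pytest.approx(oracle[key], abs=1e-12)


def test_planted_pair_ranks_first_almost_always():
    hits = 0
    for s in range(100):
        rng = np.random.default_rng(500 + s)
        X, y = _planted_data(rng, n=200, p=6, d=3.0, k=2)
        couples = score_couples(X, y, inner_folds=5, seed=s)
        best = max(couples, key=lambda c: (c.score, -c.i, -c.j))
        hits += (best.i, best.j) == (0, 1)
    assert hits >= 95


def test_too_many_features_guard(rng):
    X, y = _planted_data(rng, p=6)
    with pytest.raises(TooManyFeaturesError, match="pre-filter"):
        score_couples(X, y, p_max=5)
    with pytest.raises(ValueError):
        score_couples(X[:, :1], y)


# ---------------------------------------------------------------------------
# network construction


def test_components_from_retained_edges():
    couples = [CoupleScore(0, 1, 0.9), CoupleScore(1, 2, 0.8),
               CoupleScore(3, 4, 0.7), CoupleScore(0, 4, 0.1)]
    net = build_network(couples, keep_fraction=0.75,
                        feature_names=list("abcde"))
    assert net.components == [[0, 1, 2], [3, 4]]
    assert len(net.edges) == 3


def test_keep_all_couples_yields_single_component(rng):
    X, y = _planted_data(rng, p=5)
    couples = score_couples(X, y, inner_folds=3, seed=1)
    net = build_network(couples, keep_fraction=1.0)
    assert net.components == [[0, 1, 2, 3, 4]]


def test_equal_scores_broken_by_index_order():
    couples = [CoupleScore(i, j, 0.5) for i in range(4) for j in range(i + 1, 4)]
    net = build_network(couples, keep_fraction=0.3)  # ceil(0.3 * 6) = 2 edges
    assert [(i, j) for i, j, _ in net.edges] == [(0, 1), (0, 2)]


def test_empty_couple_list_rejected():
    with pytest.raises(ValueError):
        build_network([], 0.5)


def test_keep_fraction_monotonicity(rng):
    X, y = _planted_data(rng, p=8)
    couples = score_couples(X, y, inner_folds=3, seed=3)
    previous: set = set()
    for frac in (0.1, 0.2, 0.4, 0.7, 1.0):
        edges = {(i, j) for i, j, _ in build_network(couples, frac).edges}
        assert previous <= edges
        previous = edges


def test_components_match_transitive_closure_oracle(rng):
    for trial in range(30):
        n_edges = int(rng.integers(1, 100))
        edges = {tuple(sorted(rng.integers(0, 25, 2))) for _ in range(n_edges)}
        edges = [(i, j) for i, j in edges if i != j]
        if not edges:
            continue
        couples = [CoupleScore(i, j, float(rng.random())) for i, j in edges]
        net = build_network(couples, keep_fraction=1.0)
        ours = sorted((frozenset(int(v) for v in comp) for comp in net.components),
                      key=sorted)
        oracle = sorted((frozenset(int(v) for v in comp)
                         for comp in naive_components(edges)), key=sorted)
        assert ours == oracle


def test_hard_score_threshold_retention():
    couples = [CoupleScore(0, 1, 0.9), CoupleScore(1, 2, 0.5), CoupleScore(2, 3, 0.2)]
    net = build_network(couples, score_threshold=0.5)
    assert [(i, j) for i, j, _ in net.edges] == [(0, 1), (1, 2)]


# ---------------------------------------------------------------------------
# signature evaluation


def test_strong_signal_component_scores_high(rng):
    X, y = _planted_data(rng, n=200, p=3, d=2.0, k=3)
    assert evaluate_signature(X, y, seed=0) > 0.8


def test_noise_component_scores_near_zero():
    scores = []
    for s in range(100):
        rng = np.random.default_rng(2000 + s)
        X = rng.normal(size=(100, 3))
        y = np.tile([0, 1], 50)
        scores.append(evaluate_signature(X, y, seed=s))
    assert abs(np.mean(scores)) < 0.15


def test_single_feature_component_runs(rng):
    X, y = _planted_data(rng, n=60, p=2, d=1.0, k=1)
    score = evaluate_signature(X[:, 0], y, seed=0)
    assert -1.0 <= score <= 1.0


# ---------------------------------------------------------------------------
# procedures


_FAST = DNetProConfig(inner_folds=3, eval_folds=3, outer_folds=3, seed=9)


def test_procedure_a_deterministic(rng):
    X, y = _planted_data(rng, n=90, p=10, d=1.5)
    sig1, res1 = procedure_a(X, y, config=_FAST)
    sig2, res2 = procedure_a(X, y, config=_FAST)
    assert sig1.features == sig2.features
    np.testing.assert_array_equal(res1.scores, res2.scores)
    assert sig1.procedure == "A"
    assert len(res1.scores) == 3


def test_procedure_a_null_median_near_zero():
    medians = []
    for s in range(5):
        rng = np.random.default_rng(3000 + s)
        X = rng.normal(size=(100, 10))
        y = np.tile([0, 1], 50)
        cfg = DNetProConfig(inner_folds=3, eval_folds=3, outer_folds=4, seed=s)
        _, res = procedure_a(X, y, config=cfg)
        medians.append(np.median(res.scores))
    assert abs(np.mean(medians)) < 0.15


def test_procedure_b_minimal_balanced_cohort(rng):
    X = rng.normal(size=(9, 4))
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1])
    X[:, 0] += 2.0 * y
    sig, res = procedure_b(X, y, config=DNetProConfig(inner_folds=2, seed=0))
    assert sig.procedure == "B"
    assert len(res.scores) == 3


def test_procedure_b_too_small_cohort_errors(rng):
    X = rng.normal(size=(5, 4))
    y = np.array([0, 0, 1, 1, 1])
    with pytest.raises(PartitionError):
        procedure_b(X, y)


def test_procedure_b_deterministic(rng):
    X, y = _planted_data(rng, n=90, p=8, d=1.5)
    sig1, res1 = procedure_b(X, y, config=_FAST)
    sig2, res2 = procedure_b(X, y, config=_FAST)
    assert sig1.features == sig2.features
    np.testing.assert_array_equal(res1.scores, res2.scores)


# ---------------------------------------------------------------------------
# export


def _star_signature():
    from radsignet import Signature, SignatureNetwork

    names = ["hub", "l1", "l2", "l3", "l4"]
    edges = [(0, k, 0.5 + k / 10) for k in range(1, 5)]
    net = SignatureNetwork(names, edges, [[0, 1, 2, 3, 4]])
    return Signature(names, net, 0.7, "A")


def test_export_star_centrality_and_roundtrip(tmp_path):
    paths = export_signature(_star_signature(), tmp_path, "star")
    import pandas as pd

    nodes = pd.read_csv(paths["nodes"]).set_index("feature")
    assert nodes.loc["hub", "degree_centrality"] == pytest.approx(1.0)
    assert nodes.loc["l1", "degree_centrality"] == pytest.approx(0.25)
    assert bool(nodes.loc["hub", "is_hub"]) and not bool(nodes.loc["l1", "is_hub"])

    g = nx.read_graphml(paths["graphml"])
    assert nx.is_isomorphic(g, _star_signature().network.to_networkx())
    weights = sorted(d["weight"] for _, _, d in g.edges(data=True))
    assert weights == pytest.approx([0.6, 0.7, 0.8, 0.9])


def test_export_single_edge_degrees(tmp_path):
    from radsignet import Signature, SignatureNetwork

    net = SignatureNetwork(["a", "b"], [(0, 1, 0.4)], [[0, 1]])
    paths = export_signature(Signature(["a", "b"], net, 0.4, "B"), tmp_path, "pair")
    import pandas as pd

    nodes = pd.read_csv(paths["nodes"])
    assert nodes.degree.tolist() == [1, 1]
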