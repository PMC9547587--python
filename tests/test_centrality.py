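import math
import random

import networkx as nx
import pytest

from mirdmap.centrality import (
    MEASURES,
    build_graph,
    centrality_suite,
    consensus,
    epc,
    rank_scores,
)


def star():
    return build_graph([("c", f"l{i}", 1.0) for i in range(4)])


def triangle(w=1.0):
    return build_graph([("a", "b", w), ("b", "c", w), ("a", "c", w)])


@pytest.fixture(scope="module")
def fixture50():
    """Fixed 50-node random weighted graph for stability checks."""
    rng = random.Random(13)
    edges = []
    for u in range(50):
        for v in range(u + 1, 50):
            if rng.random() < 0.12:
                edges.append((f"n{u:02d}", f"n{v:02d}", 1.0 + 9.0 * rng.random()))
    return build_graph(edges)


class TestSuiteHandValues:
    def test_star_center(self):
        s = centrality_suite(star())
        assert s["degree"]["c"] == 4.0
        assert s["betweenness"]["c"] == pytest.approx(6.0)  # C(4,2) leaf pairs
        assert all(s["betweenness"][f"l{i}"] == 0.0 for i in range(4))
        assert s["closeness"]["c"] > max(s["closeness"][f"l{i}"] for i in range(4))

    def test_triangle_network_and_local_average(self):
        s = centrality_suite(triangle())
        for v in "abc":
            assert s["network"][v] == pytest.approx(2.0)
            assert s["local_average"][v] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "g", [nx.cycle_graph(6), nx.complete_graph(5)], ids=["C6", "K5"]
    )
    def test_vertex_transitive_graphs_score_uniformly(self, g):
        wg = build_graph([(str(u), str(v), 1.0) for u, v in g.edges])
        for measure, scores in centrality_suite(wg).items():
            vals = list(scores.values())
            assert max(vals) - min(vals) < 1e-9, measure

    def test_weight_scaling(self):
        s1 = centrality_suite(triangle(1.0))
        s2 = centrality_suite(triangle(2.0))
        for v in "abc":
            assert s2["degree"][v] == 2 * s1["degree"][v]
        assert rank_scores(s2["eigenvector"]) == rank_scores(s1["eigenvector"])

    def test_isolated_component_handling(self):
        g = build_graph([("a", "b", 1.0), ("c", "d", 1.0), ("d", "e", 1.0)])
        s = centrality_suite(g)
        assert set(s["betweenness"]) == {"a", "b", "c", "d", "e"}
        assert s["betweenness"]["d"] == 1.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            centrality_suite(nx.Graph())

    def test_scores_are_stable_across_runs(self, fixture50):
        s1 = centrality_suite(fixture50)
        s2 = centrality_suite(fixture50)
        for m in MEASURES:
            for v in s1[m]:
                assert s1[m][v] == pytest.approx(s2[m][v], abs=1e-9)


class TestBuildGraph:
    def test_inf_weight_replaced_by_max_finite(self):
        g = build_graph([("a", "b", math.inf), ("b", "c", 5.0)])
        assert g["a"]["b"]["weight"] == 5.0

    def test_self_loop_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            build_graph([("a", "a", 1.0)])
        with pytest.raises(ValueError):
            build_graph([("a", "b", 0.0)])


class TestEpc:
    def test_single_edge_full_retention_symmetric(self):
        g = build_graph([("x", "y", 3.0)])
        assert epc(g, reps=20, seed=1, retain=1.0) == {"x": 1.0, "y": 1.0}

    def test_disjoint_triangles_symmetric_within_blocks(self):
        g = build_graph(
            [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
             ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0)]
        )
        scores = epc(g, reps=4000, seed=5)
        for block in ("abc", "xyz"):
            vals = [scores[v] for v in block]
            assert max(vals) - min(vals) < 0.1

    def test_star_center_beats_path_middle(self):
        star5 = build_graph([("c", f"l{i}", 1.0) for i in range(4)])
        path5 = build_graph([(f"p{i}", f"p{i+1}", 1.0) for i in range(4)])
        s = epc(star5, reps=2000, seed=7)
        p = epc(path5, reps=2000, seed=7)
        assert s["c"] > p["p2"]

    def test_deterministic_given_seed(self, fixture50):
        assert epc(fixture50, reps=50, seed=9) == epc(fixture50, reps=50, seed=9)


def rank_fixture(n_top_lists: dict[str, int], n_measures: int = 7, top_t: int = 3):
    """Scores where node X appears in exactly n_top_lists[X] top-T lists."""
    fillers = [f"f{i}" for i in range(top_t + 2)]
    scores = {}
    for m in range(n_measures):
        sc = {}
        listed = [v for v, k in n_top_lists.items() if m < k]
        rank = 0
        for v in listed:
            sc[v] = 100.0 - rank
            rank += 1
        for f in fillers:
            sc[f] = 50.0 - rank
            rank += 1
        scores[f"measure{m}"] = sc
    return scores


class TestConsensus:
    def test_unanimous_node_has_full_agreement(self):
        scores = rank_fixture({"hub": 7}, top_t=3)
        rep = consensus(scores, top_t=3, min_agreement=5)
        assert rep.agreement["hub"] == 7
        assert "hub" in rep.consensus

    def test_agreement_boundary_five_in_four_out(self):
        scores = rank_fixture({"five": 5, "four": 4}, top_t=3)
        rep = consensus(scores, top_t=3, min_agreement=5)
        assert rep.agreement["five"] == 5 and rep.agreement["four"] == 4
        assert "five" in rep.consensus and "four" not in rep.consensus

    def test_measure_order_invariance(self, fixture50):
        scores = centrality_suite(fixture50)
        rep1 = consensus(scores, top_t=10, min_agreement=5)
        shuffled = dict(reversed(list(scores.items())))
        rep2 = consensus(shuffled, top_t=10, min_agreement=5)
        assert rep1.consensus == rep2.consensus
        assert rep1.agreement == rep2.agreement

    def test_monotone_in_min_agreement(self, fixture50):
        scores = centrality_suite(fixture50)
        strict = set(consensus(scores, top_t=10, min_agreement=6).consensus)
        loose = set(consensus(scores, top_t=10, min_agreement=5).consensus)
        assert strict <= loose

    def test_rank_permutation_with_name_tiebreak(self):
        ranks = rank_scores({"b": 1.0, "a": 1.0, "c": 2.0})
        assert ranks == {"c": 1, "a": 2, "b": 3}

    def test_bad_arguments(self, fixture50):
        scores = centrality_suite(fixture50)
        with pytest.raises(ValueError):
            consensus(scores, top_t=0)
        with pytest.raises(ValueError):
            consensus(scores, min_agreement=8)
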