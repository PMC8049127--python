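import itertools
import math

import networkx as nx
import numpy as np
import pytest

from conftest import random_distance_matrix
from stadnet import (
    DataError,
    DistanceMatrix,
    EdgeCandidate,
    build_mst,
    edge_ratio,
    evaluate_prefix,
    hop_distance_matrix,
    network_correlation,
    oracle_best_prefix,
    rank_edge_candidates,
    run_stad_r,
)


def dist_from_array(values):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(tuple(f"n{i}" for i in range(len(values))), values)


def path_distance_matrix(n, near=0.1, far=0.9):
    v = np.full((n, n), far)
    for i in range(n - 1):
        v[i, i + 1] = v[i + 1, i] = near
    np.fill_diagonal(v, 0.0)
    return dist_from_array(v)


class TestCandidatesAndMst:
    def test_all_pairs_sorted_by_distance(self):
        dist = dist_from_array([[0, 0.5, 0.2], [0.5, 0, 0.8], [0.2, 0.8, 0]])
        cands = rank_edge_candidates(dist)
        assert [(c.node_a, c.node_b) for c in cands] == [(0, 2), (0, 1), (1, 2)]
        assert [c.distance for c in cands] == sorted(c.distance for c in cands)

    def test_equal_distances_fall_back_to_lexicographic(self):
        dist = dist_from_array(np.ones((4, 4)) - np.eye(4))
        pairs = [(c.node_a, c.node_b) for c in rank_edge_candidates(dist)]
        assert pairs == sorted(itertools.combinations(range(4), 2))

    def test_two_nodes_single_candidate(self):
        dist = dist_from_array([[0, 0.3], [0.3, 0]])
        cands = rank_edge_candidates(dist)
        assert len(cands) == 1 and cands[0].in_mst

    def test_path_shaped_matrix_yields_chain(self):
        net = build_mst(path_distance_matrix(4))
        chain = {(0, 1), (1, 2), (2, 3)}
        assert {(e.node_a, e.node_b) for e in net.edges} == chain
        assert all(e.in_mst for e in net.edges)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_mst_weight_minimal_over_all_spanning_trees(self, n, rng):
        dist = random_distance_matrix(rng, n)
        mst_weight = sum(e.distance for e in build_mst(dist).edges)
        pairs = list(itertools.combinations(range(n), 2))
        best = math.inf
        for tree in itertools.combinations(pairs, n - 1):
            g = nx.Graph(tree)
            if g.number_of_nodes() == n and nx.is_connected(g):
                best = min(best, sum(dist.values[a, b] for a, b in tree))
        assert mst_weight == pytest.approx(best)


class TestHopsAndCorrelation:
    def triangle(self):
        edges = (
            EdgeCandidate(0, 1, 0.1, True),
            EdgeCandidate(1, 2, 0.1, True),
            EdgeCandidate(0, 2, 0.2, False),
        )
        from stadnet import StadNetwork

        return StadNetwork(("a", "b", "c"), edges, added_edge_count=1)

    def test_triangle_all_hops_one(self):
        hops = hop_distance_matrix(self.triangle())
        assert np.all(hops[~np.eye(3, dtype=bool)] == 1)
        assert np.all(np.diag(hops) == 0)

    def test_path_graph_max_hops(self):
        net = build_mst(path_distance_matrix(4))
        hops = hop_distance_matrix(net)
        assert hops.max() == 3
        assert np.allclose(hops, hops.T)

    def test_adding_edges_never_increases_hops(self, rng):
        dist = random_distance_matrix(rng, 7)
        ranked = rank_edge_candidates(dist)
        mst = [e for e in ranked if e.in_mst]
        extra = [e for e in ranked if not e.in_mst]
        from stadnet import StadNetwork

        prev = None
        for k in range(len(extra) + 1):
            net = StadNetwork(dist.ids, tuple(mst + extra[:k]), k)
            hops = hop_distance_matrix(net)
            if prev is not None:
                assert np.all(hops <= prev)
            prev = hops

    def test_perfect_linear_relation_gives_unit_correlation(self):
        dist = path_distance_matrix(4, near=0.25, far=0.75)
        hops = hop_distance_matrix(build_mst(dist))
        # hop matrix of the chain is |i-j|; make D_X affine in it
        v = np.abs(np.subtract.outer(range(4), range(4))) * 0.2
        assert network_correlation(dist_from_array(v), hops) == pytest.approx(1.0)

    def test_correlation_invariant_to_affine_hop_rescaling(self, rng):
        dist = random_distance_matrix(rng, 6)
        hops = hop_distance_matrix(build_mst(dist)).astype(float)
        base = network_correlation(dist, hops)
        assert network_correlation(dist, 3.0 * hops + 7.0) == pytest.approx(base)

    def test_zero_variance_hop_vector_is_zero_by_convention(self, rng):
        dist = random_distance_matrix(rng, 3)
        complete = np.ones((3, 3)) - np.eye(3)
        with pytest.warns(UserWarning, match="zero-variance"):
            assert network_correlation(dist, complete) == 0.0

    def test_matches_direct_pearson_on_four_nodes(self, rng):
        dist = random_distance_matrix(rng, 4)
        hops = hop_distance_matrix(build_mst(dist))
        iu = np.triu_indices(4, 1)
        expected = np.corrcoef(dist.values[iu], hops[iu])[0, 1]
        assert network_correlation(dist, hops) == pytest.approx(expected)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(DataError):
            network_correlation(random_distance_matrix(rng, 4), np.zeros((3, 3)))


class TestEdgeRatio:
    @pytest.mark.parametrize(
        "distances, expected",
        [([0.0, 0.0, 0.0], 1.0), ([1.0, 1.0], 0.0), ([0.5], 1 / 3)],
    )
    def test_known_values(self, distances, expected):
        assert edge_ratio(distances) == pytest.approx(expected)

    def test_always_within_unit_interval(self, rng):
        for _ in range(200):
            d = rng.random(int(rng.integers(1, 30)))
            assert 0.0 <= edge_ratio(d) <= 1.0

    def test_empty_edge_set_rejected(self):
        with pytest.raises(DataError):
            edge_ratio([])


class TestPrefixSearch:
    def test_zero_added_edges_is_pure_mst(self, rng):
        dist = random_distance_matrix(rng, 6)
        ranked = rank_edge_candidates(dist)
        point = evaluate_prefix(dist, ranked, 0)
        mst = build_mst(dist)
        hops = hop_distance_matrix(mst)
        assert point.added_edges == 0
        assert point.rho == pytest.approx(network_correlation(dist, hops))
        assert point.ratio_r == pytest.approx(edge_ratio(mst.edges))

    def test_objective_is_product_of_factors(self, rng):
        dist = random_distance_matrix(rng, 6)
        ranked = rank_edge_candidates(dist)
        for k in (0, 3, len(ranked) - 5):
            point = evaluate_prefix(dist, ranked, k)
            assert point.objective == point.rho * point.ratio_r

    def test_out_of_range_prefix_rejected(self, rng):
        dist = random_distance_matrix(rng, 5)
        ranked = rank_edge_candidates(dist)
        with pytest.raises(DataError):
            evaluate_prefix(dist, ranked, len(ranked))

    def test_exhaustive_matches_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            dist = random_distance_matrix(rng, n)
            net, trace = run_stad_r(dist, mode="exhaustive")
            oracle = oracle_best_prefix(dist)
            assert trace.best.objective == oracle.objective
            assert trace.best.added_edges == oracle.added_edges
            assert net.added_edge_count == oracle.added_edges

    def test_network_contains_mst_and_is_connected(self, rng):
        for mode in ("exhaustive", "coarse"):
            dist = random_distance_matrix(rng, 8)
            net, _ = run_stad_r(dist, mode=mode)
            mst_pairs = {(e.node_a, e.node_b) for e in build_mst(dist).edges}
            net_pairs = {(e.node_a, e.node_b) for e in net.edges}
            assert mst_pairs <= net_pairs
            assert np.isfinite(hop_distance_matrix(net)).all()

    def test_best_at_least_as_good_as_mst(self, rng):
        dist = random_distance_matrix(rng, 8)
        _, trace = run_stad_r(dist, mode="exhaustive")
        assert trace.best.objective >= trace.points[0].objective
        assert trace.points[0].added_edges == 0

    def test_deterministic_across_runs(self, rng):
        dist = random_distance_matrix(rng, 12)
        net1, trace1 = run_stad_r(dist, mode="coarse")
        net2, trace2 = run_stad_r(dist, mode="coarse")
        assert trace1.points == trace2.points
        assert net1.edges == net2.edges

    def test_constant_distances_return_mst(self):
        dist = dist_from_array(0.5 * (np.ones((5, 5)) - np.eye(5)))
        net, trace = run_stad_r(dist, mode="exhaustive")
        assert net.added_edge_count == 0
        assert trace.best.rho == 0.0

    def test_first_argmax_wins_under_ties(self):
        dist = dist_from_array(0.5 * (np.ones((5, 5)) - np.eye(5)))
        oracle = oracle_best_prefix(dist)
        assert oracle.added_edges == 0

    def test_oracle_refuses_large_instances(self, rng):
        with pytest.raises(DataError):
            oracle_best_prefix(random_distance_matrix(rng, 12))

    def test_pure_correlation_objective_keeps_more_edges_on_skewed_data(self):
        from stadnet import SynthConfig, generate_cohort, profiles_to_distance

        profiles, _ = generate_cohort(SynthConfig(n_patients=60, seed=5))
        dist = profiles_to_distance(profiles)
        net_ratio, _ = run_stad_r(dist, objective="ratio")
        net_rho, _ = run_stad_r(dist, objective="correlation")
        assert net_ratio.added_edge_count < net_rho.added_edge_count

    def test_trace_round_trip_marks_best_row(self, tmp_path, rng):
        import pandas as pd

        dist = random_distance_matrix(rng, 6)
        _, trace = run_stad_r(dist, mode="exhaustive")
        path = tmp_path / "trace.csv"
        trace.write(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == [
            "added_edges", "rho", "ratio_r", "objective", "is_best",
        ]
        assert frame["is_best"].sum() == 1
        best_row = frame[frame["is_best"]].iloc[0]
        assert best_row["added_edges"] == trace.best.added_edges
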