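import numpy as np
import pytest
from scipy.linalg import expm

from sfgrad.atlas import Parcel, ParcelAtlas, euclidean_distance_matrix
from sfgrad.matrix import ConnectivityMatrix
from sfgrad.structural import (
    AggregationOptions,
    aggregate_counts,
    aggregate_lengths,
    cosine_profiles,
    flow_graph,
    matching_index,
    mean_first_passage_time,
    min_hop_count,
    navigate,
    search_information,
    shortest_path_length_mm,
    strength,
)
from oracles import (
    cosine_oracle,
    matching_oracle,
    mfpt_oracle,
    navigation_oracle,
)


def cm(values, **kw):
    return ConnectivityMatrix(np.asarray(values, float), **kw)


def line_atlas(xs):
    return ParcelAtlas(
        [Parcel(i, f"p{i}", "r", (float(x), 0.0, 0.0), 1.0) for i, x in enumerate(xs)]
    )


class TestAggregation:
    def test_volume_normalized_mean(self, toy_atlas):
        subj = [cm([[0, 2, 0], [2, 0, 0], [0, 0, 0]]), cm([[0, 4, 0], [4, 0, 0], [0, 0, 0]])]
        out = aggregate_counts(subj, toy_atlas)
        # mean 3 over geometric mean volume sqrt(8*2)=4
        assert out.values[0, 1] == pytest.approx(0.75)

    def test_no_threshold_keeps_single_subject_connection(self, toy_atlas):
        subj = [cm(np.zeros((3, 3))) for _ in range(9)] + [cm([[0, 1, 0], [1, 0, 0], [0, 0, 0]])]
        out = aggregate_counts(subj, toy_atlas, AggregationOptions(volume_normalize=False))
        assert out.values[0, 1] == pytest.approx(0.1)  # kept: nonzero in 1 of 10

    def test_threshold_zeroes_rare_connections(self, toy_atlas):
        subj = [cm(np.zeros((3, 3))) for _ in range(9)] + [cm([[0, 1, 0], [1, 0, 0], [0, 0, 0]])]
        out = aggregate_counts(
            subj, toy_atlas, AggregationOptions(zero_threshold_fraction=0.5, volume_normalize=False)
        )
        assert out.values[0, 1] == 0.0

    def test_matches_pair_loop(self, toy_atlas):
        rng = np.random.default_rng(0)
        subj = []
        for _ in range(3):
            a = rng.integers(0, 5, size=(3, 3)).astype(float)
            subj.append(cm(np.triu(a, 1) + np.triu(a, 1).T))
        out = aggregate_counts(subj, toy_atlas)
        vols = toy_atlas.volumes
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                expect = np.mean([s.values[i, j] for s in subj]) / np.sqrt(vols[i] * vols[j])
                assert out.values[i, j] == pytest.approx(expect)

    def test_length_weighting(self, toy_atlas):
        subj = [cm([[0, 2, 0], [2, 0, 0], [0, 0, 0]])]
        lengths = cm([[np.nan, 10, np.nan], [10, np.nan, np.nan], [np.nan, np.nan, np.nan]])
        base = aggregate_counts(subj, toy_atlas)
        mult = aggregate_counts(
            subj, toy_atlas, AggregationOptions(length_weighting="multiply"), lengths=lengths
        )
        div = aggregate_counts(
            subj, toy_atlas, AggregationOptions(length_weighting="divide"), lengths=lengths
        )
        assert mult.values[0, 1] == pytest.approx(base.values[0, 1] * 10)
        assert div.values[0, 1] == pytest.approx(base.values[0, 1] / 10)


class TestLengths:
    def test_mean_over_connected_subjects(self):
        counts = [cm([[0, 1], [1, 0]]), cm([[0, 2], [2, 0]])]
        lens = [cm([[np.nan, 10], [10, np.nan]]), cm([[np.nan, 20], [20, np.nan]])]
        out = aggregate_lengths(lens, counts)
        assert out.values[0, 1] == pytest.approx(15.0)

    def test_never_connected_is_missing(self):
        counts = [cm(np.zeros((2, 2)))]
        lens = [cm([[np.nan, np.nan], [np.nan, np.nan]])]
        assert np.isnan(aggregate_lengths(lens, counts).values[0, 1])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        counts, lens = [], []
        for _ in range(4):
            c = rng.integers(0, 2, size=(5, 5)).astype(float)
            c = np.triu(c, 1) + np.triu(c, 1).T
            l = np.where(c > 0, rng.uniform(5, 50, size=(5, 5)), np.nan)
            l = np.triu(l, 1) + np.triu(l, 1).T
            counts.append(cm(c))
            lens.append(cm(l))
        out = aggregate_lengths(lens, counts)
        for i in range(5):
            for j in range(i + 1, 5):
                vals = [
                    lens[s].values[i, j]
                    for s in range(4)
                    if counts[s].values[i, j] > 0
                ]
                if vals:
                    assert out.values[i, j] == pytest.approx(np.mean(vals))
                else:
                    assert np.isnan(out.values[i, j])


class TestCosineProfiles:
    def test_identical_rows(self):
        w = cm([[0, 0, 1, 2], [0, 0, 1, 2], [1, 1, 0, 0], [2, 2, 0, 0]])
        assert cosine_profiles(w).values[0, 1] == pytest.approx(1.0)

    def test_orthogonal_support(self):
        w = cm([[0, 0, 1, 0], [0, 0, 0, 1], [1, 0, 0, 0], [0, 1, 0, 0]])
        assert cosine_profiles(w).values[0, 1] == pytest.approx(0.0)

    def test_masked_closed_form(self):
        # profiles after masking: (1,0) and (1,1) -> cos = 1/sqrt(2)
        w = cm([[0, 0, 1, 0], [0, 0, 1, 1], [1, 1, 0, 0], [0, 1, 0, 0]])
        assert cosine_profiles(w).values[0, 1] == pytest.approx(1 / np.sqrt(2))

    def test_matches_loop_oracle(self, graph_factory):
        g = graph_factory(np.random.default_rng(2), 6)
        out = cosine_profiles(g).values
        for i in range(6):
            for j in range(i + 1, 6):
                assert out[i, j] == pytest.approx(
                    cosine_oracle(g.values, i, j), abs=1e-10, nan_ok=True
                )


class TestMatchingIndex:
    def test_identical_neighborhoods(self):
        w = cm([[0, 0, 1, 2], [0, 0, 1, 2], [1, 1, 0, 0], [2, 2, 0, 0]])
        assert matching_index(w).values[0, 1] == pytest.approx(1.0)

    def test_disjoint_neighborhoods(self):
        w = cm([[0, 0, 1, 0], [0, 0, 0, 1], [1, 0, 0, 0], [0, 1, 0, 0]])
        assert matching_index(w).values[0, 1] == pytest.approx(0.0)

    def test_matches_loop_oracle(self, graph_factory):
        g = graph_factory(np.random.default_rng(3), 6)
        out = matching_index(g).values
        for i in range(6):
            for j in range(i + 1, 6):
                assert out[i, j] == pytest.approx(matching_oracle(g.values, i, j), abs=1e-10)


class TestFlowGraph:
    def test_t0_has_zero_offdiagonal(self, graph_factory):
        g = graph_factory(np.random.default_rng(4), 5)
        f = flow_graph(g, t=0.0)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(f.values[off], 0.0, atol=1e-12)

    def test_conservation_against_direct_propagator(self, graph_factory):
        g = graph_factory(np.random.default_rng(5), 6)
        a = np.where(np.isnan(g.values), 0.0, g.values)
        np.fill_diagonal(a, 0.0)
        s = a.sum(axis=1)
        p = a / s[:, None]
        full = np.diag(s) @ expm(1.0 * (p - np.eye(6)))
        full = (full + full.T) / 2
        assert full.sum() == pytest.approx(s.sum())  # probability conservation
        out = flow_graph(g, t=1.0).values
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(out[off], full[off], atol=1e-10)

    def test_two_node_closed_form(self):
        # P - I = [[-1, 1], [1, -1]]: expm(t(P-I)) has entries
        # (1 ± exp(-2t))/2; with equal strengths s the flow is s*(1-exp(-2))/2
        w = cm([[0, 2.0], [2.0, 0]])
        f = flow_graph(w, t=1.0)
        assert f.values[0, 1] == pytest.approx(2.0 * (1 - np.exp(-2.0)) / 2.0)

    def test_disconnected_rejected(self):
        w = cm([[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]])
        with pytest.raises(ValueError, match="disconnected"):
            flow_graph(w)


class TestNavigation:
    def test_forced_chain_route(self):
        at = line_atlas([0.0, 1.0, 2.0])
        counts = cm([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        nav_count, _ = navigate(counts, euclidean_distance_matrix(at))
        assert nav_count.values[0, 2] == pytest.approx(2.0)

    def test_direct_edge(self):
        at = line_atlas([0.0, 1.0])
        counts = cm([[0, 1], [1, 0]])
        nav_count, _ = navigate(counts, euclidean_distance_matrix(at))
        assert nav_count.values[0, 1] == pytest.approx(1.0)

    def test_matches_simulator_oracle(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 10, size=(8, 3))
        at = ParcelAtlas([Parcel(i, f"p{i}", "r", tuple(coords[i]), 1.0) for i in range(8)])
        d = euclidean_distance_matrix(at)
        adj = (d.values < 6) & ~np.eye(8, dtype=bool)
        w = np.where(adj, rng.uniform(0.5, 2, size=(8, 8)), 0.0)
        w = np.triu(w, 1) + np.triu(w, 1).T
        counts = cm(w)
        lengths_v = np.where(w > 0, np.nan_to_num(d.values) * 1.1, np.nan)
        np.fill_diagonal(lengths_v, np.nan)
        lengths = cm(lengths_v)
        nav_count, nav_length = navigate(counts, d, lengths)
        oh, ol = navigation_oracle(w, d.values, np.nan_to_num(lengths_v))
        oh_s = (oh + oh.T) / 2
        ol_s = (ol + ol.T) / 2
        np.testing.assert_allclose(nav_count.values, oh_s, equal_nan=True, atol=1e-10)
        np.testing.assert_allclose(nav_length.values, ol_s, equal_nan=True, atol=1e-10)


class TestSearchInformation:
    def test_two_node_zero_bits(self):
        w = cm([[0, 3.0], [3.0, 0]])
        assert search_information(w).values[0, 1] == pytest.approx(0.0)

    def test_star_leaf_to_leaf(self):
        k = 4
        w = np.zeros((k + 1, k + 1))
        w[0, 1:] = w[1:, 0] = 1.0
        si = search_information(cm(w))
        assert si.values[1, 2] == pytest.approx(np.log2(k))

    def test_unreachable_missing(self):
        w = cm([[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]])
        assert np.isnan(search_information(w).values[0, 2])


class TestMFPT:
    def test_two_node_single_edge(self):
        assert mean_first_passage_time(cm([[0, 1.0], [1.0, 0]])).values[0, 1] == pytest.approx(1.0)

    def test_three_node_path(self):
        # a-b-c unit weights: from a, E[steps to c] solves h_a=1+h_b,
        # h_b=1+h_a/2 -> h_a=4; symmetric, so the symmetrized value is 4
        w = cm([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        assert mean_first_passage_time(w).values[0, 2] == pytest.approx(4.0)

    def test_matches_fundamental_matrix(self, graph_factory):
        g = graph_factory(np.random.default_rng(7), 6)
        out = mean_first_passage_time(g).values
        exp = mfpt_oracle(g.values)
        np.testing.assert_allclose(out, exp, equal_nan=True, atol=1e-8)


class TestShortestPathLength:
    def test_direct_beats_detour(self):
        counts = cm([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        lens = cm([[np.nan, 12, 7], [12, np.nan, 8], [7, 8, np.nan]])
        assert shortest_path_length_mm(counts, lens).values[0, 1] == pytest.approx(12.0)

    def test_detour_beats_direct(self):
        counts = cm([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        lens = cm([[np.nan, 12, 5], [12, np.nan, 5], [5, 5, np.nan]])
        assert shortest_path_length_mm(counts, lens).values[0, 1] == pytest.approx(10.0)

    def test_negative_length_rejected(self):
        counts = cm([[0, 1], [1, 0]])
        lens = cm([[np.nan, -1.0], [-1.0, np.nan]])
        with pytest.raises(ValueError, match="negative"):
            shortest_path_length_mm(counts, lens)


class TestHopCount:
    def test_direct_and_chain(self):
        w = cm([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        out = min_hop_count(w).values
        assert out[0, 1] == 1 and out[0, 2] == 2

    def test_unreachable_missing(self):
        w = cm([[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]])
        assert np.isnan(min_hop_count(w).values[0, 3])

    def test_adding_edge_never_increases(self, graph_factory):
        rng = np.random.default_rng(8)
        g = graph_factory(rng, 7)
        before = min_hop_count(g).values
        w = g.values.copy()
        w = np.where(np.isnan(w), 0.0, w)
        zeros = [(i, j) for i in range(7) for j in range(i + 1, 7) if w[i, j] == 0]
        if zeros:
            i, j = zeros[0]
            w[i, j] = w[j, i] = 1.0
        after = min_hop_count(cm(w)).values
        off = ~np.eye(7, dtype=bool)
        assert np.all(after[off] <= before[off] + 1e-12)


class TestStrength:
    def test_all_ones(self):
        w = cm(np.ones((3, 3)))
        np.testing.assert_allclose(strength(w), [2, 2, 2])

    def test_zeros(self):
        np.testing.assert_allclose(strength(cm(np.zeros((4, 4)))), np.zeros(4))

    def test_matches_loop(self, graph_factory):
        g = graph_factory(np.random.default_rng(9), 6)
        out = strength(g)
        a = np.where(np.isnan(g.values), 0, g.values)
        for i in range(6):
            assert out[i] == pytest.approx(sum(a[i, j] for j in range(6) if j != i))
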