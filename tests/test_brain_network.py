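"""Filtering, Granger causality, maximum spanning tree and tree metrics."""

import itertools

import networkx as nx
import numpy as np
import pytest

from eegfuse import brain_network as bn
from eegfuse.brain_network import (
    BANDS,
    ConnectivityMatrix,
    EpochSignal,
    bandpass,
    connectivity,
    fit_var,
    max_spanning_tree,
    mst_metrics,
    pairwise_gc,
    subject_features,
)
from naive_oracles import brute_tree_metrics, tree_from_pruefer, all_spanning_trees_best

FS = 512.0


def _amplitude(x):
    core = x[512:-512]
    return np.sqrt(2.0 * np.mean(core**2))


class TestBandpass:
    def test_passband_tone_preserved(self):
        t = np.arange(4096) / FS
        epoch = EpochSignal(np.sin(2 * np.pi * 6.0 * t)[None, :], FS)
        out = bandpass(epoch, BANDS["theta"])
        assert _amplitude(out.samples[0]) == pytest.approx(1.0, rel=0.05)

    def test_stopband_tone_suppressed_40db(self):
        t = np.arange(4096) / FS
        epoch = EpochSignal(np.sin(2 * np.pi * 20.0 * t)[None, :], FS)
        out = bandpass(epoch, BANDS["theta"])
        assert _amplitude(out.samples[0]) < 10 ** (-40 / 20)

    def test_zero_signal_stays_zero(self):
        epoch = EpochSignal(np.zeros((3, 2048)), FS)
        out = bandpass(epoch, BANDS["beta"])
        assert np.allclose(out.samples, 0.0)

    def test_shape_preserved(self):
        epoch = EpochSignal(np.random.default_rng(0).standard_normal((5, 1024)), FS)
        assert bandpass(epoch, BANDS["beta"]).samples.shape == (5, 1024)

    def test_band_outside_nyquist_rejected(self):
        epoch = EpochSignal(np.zeros((1, 1024)), 64.0)
        with pytest.raises(ValueError):
            bandpass(epoch, (30.0, 45.0))


class TestFitVar:
    def test_recovers_var2_order(self, rng):
        hits = 0
        for _ in range(20):
            A1 = np.array([[0.5, 0.2], [0.0, 0.4]])
            A2 = np.array([[-0.3, 0.0], [0.1, -0.25]])
            x = np.zeros((2, 2300))
            eps = rng.standard_normal((2, 2300))
            for t in range(2, 2300):
                x[:, t] = A1 @ x[:, t - 1] + A2 @ x[:, t - 2] + eps[:, t]
            order, _, _ = fit_var(x[:, 300:], max_order=6)
            hits += order == 2
        assert hits >= 18  # >= 90% recovery

    def test_white_noise_coefficients_near_zero(self, rng):
        x = rng.standard_normal((1, 5000))
        _, coef, _ = fit_var(x, max_order=3)
        # OLS s.e. of an AR coefficient on T samples is ~ 1/sqrt(T)
        assert np.all(np.abs(coef[0, :-1]) < 4.0 / np.sqrt(5000))

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            fit_var(np.ones((1, 500)), max_order=2)


class TestPairwiseGC:
    def test_independent_noise_near_zero(self, rng):
        x = rng.standard_normal(4096)
        y = rng.standard_normal(4096)
        # null 95% quantile of F at p lags is ~ chi2(p)/T; stay well above it
        assert pairwise_gc(x, y, order=2) < 0.01

    def test_directed_coupling_detected(self, rng):
        wins = 0
        for _ in range(30):
            y = rng.standard_normal(4097)
            e = rng.standard_normal(4096)
            x = np.zeros(4096)
            for t in range(1, 4096):
                x[t] = 0.3 * x[t - 1] + 0.5 * y[t] + e[t]  # y leads x by one lag
            f_yx = pairwise_gc(x, y[1:], order=3)
            f_xy = pairwise_gc(y[1:], x, order=3)
            wins += f_yx > f_xy
            assert f_yx > 0.0
        assert wins == 30

    def test_lagged_copy_is_strongly_causal(self, rng):
        x = rng.standard_normal(2049)
        y = x[:-1]  # y(t) = x(t-1): x's past predicts y perfectly... reversed:
        f_xy = pairwise_gc(y, x[1:], order=2)   # x -> y should be huge
        f_yx = pairwise_gc(x[1:], y, order=2)
        assert f_xy > 1.0
        assert f_yx < 0.05

    def test_non_negative(self, rng):
        for _ in range(20):
            x = rng.standard_normal(512)
            y = rng.standard_normal(512)
            assert pairwise_gc(x, y, order=4) >= -1e-12


class TestConnectivity:
    def test_single_coupling_dominates_matrix(self, rng):
        # 3 channels, only 0 -> 1 coupled
        n = 4096
        x = rng.standard_normal((3, n))
        for t in range(1, n):
            x[1, t] = 0.3 * x[1, t - 1] + 0.6 * x[0, t - 1] + 0.5 * x[1, t]
        W = connectivity(EpochSignal(x, FS), order=2).W
        assert W[1, 0] == np.max(W)
        assert W[1, 0] > 5 * np.max(W[W < W[1, 0]])

    def test_diagonal_zero_and_nonnegative(self, rng):
        W = connectivity(EpochSignal(rng.standard_normal((4, 1024)), FS), order=2).W
        assert np.all(np.diag(W) == 0.0)
        assert np.all(W >= 0.0)

    def test_channel_permutation_equivariance(self, rng):
        data = rng.standard_normal((4, 1024))
        perm = [2, 0, 3, 1]
        W = connectivity(EpochSignal(data, FS), order=2).W
        Wp = connectivity(EpochSignal(data[perm], FS), order=2).W
        assert np.allclose(Wp, W[np.ix_(perm, perm)], atol=1e-10)


class TestMaxSpanningTree:
    def test_four_node_worked_example(self):
        # weights AB:4 AC:3 AD:2 BC:1 BD:1 CD:1 -> star at A
        W = np.zeros((4, 4))
        pairs = {(0, 1): 4, (0, 2): 3, (0, 3): 2, (1, 2): 1, (1, 3): 1, (2, 3): 1}
        for (i, j), w in pairs.items():
            W[i, j] = W[j, i] = w
        tree = max_spanning_tree(W)
        assert sorted(tree.edges()) == [(0, 1), (0, 2), (0, 3)]
        # cross-check against enumeration of all 16 spanning trees
        _, best_edges = all_spanning_trees_best(pairs, 4)
        assert sorted(tree.edges()) == best_edges

    def test_matches_networkx_on_random_weights(self, rng):
        for _ in range(10):
            k = 19
            A = rng.uniform(0.1, 1.0, size=(k, k))
            A = 0.5 * (A + A.T)
            np.fill_diagonal(A, 0.0)
            tree = max_spanning_tree(A)
            assert tree.number_of_edges() == 18
            G = nx.from_numpy_array(A)
            ref = nx.maximum_spanning_tree(G, algorithm="kruskal")
            assert sorted(map(tuple, map(sorted, tree.edges()))) == sorted(
                map(tuple, map(sorted, ref.edges()))
            )

    def test_tree_input_returns_itself(self):
        A = np.zeros((5, 5))
        for i, j in [(0, 1), (1, 2), (1, 3), (3, 4)]:
            A[i, j] = A[j, i] = 1.0
        assert sorted(max_spanning_tree(A).edges()) == [(0, 1), (1, 2), (1, 3), (3, 4)]

    def test_deterministic_tie_break(self):
        A = np.ones((4, 4)) - np.eye(4)  # all ties
        tree1 = max_spanning_tree(A)
        tree2 = max_spanning_tree(A)
        assert sorted(tree1.edges()) == sorted(tree2.edges()) == [(0, 1), (0, 2), (0, 3)]

    def test_disconnected_graph_rejected(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        with pytest.raises(ValueError):
            max_spanning_tree(A)


class TestMSTMetrics:
    def test_star_closed_form(self):
        star = nx.star_graph(18)  # 19 nodes
        m = mst_metrics(star)
        assert m.max_degree == 18
        assert m.leaf_fraction == pytest.approx(18 / 19)
        assert m.diameter == 2
        assert m.max_bc == pytest.approx(1.0)
        assert m.hierarchy == pytest.approx(18 / (2 * 18 * 1.0))

    def test_path_closed_form(self):
        path = nx.path_graph(19)
        m = mst_metrics(path)
        assert m.max_degree == 2
        assert m.leaf_fraction == pytest.approx(2 / 19)
        assert m.diameter == 18
        # center of a path of 19 nodes carries the most shortest paths
        bc = nx.betweenness_centrality(path)
        assert m.max_bc == pytest.approx(bc[9])

    def test_exhaustive_oracle_small_trees(self):
        """All trees on 2..6 nodes, via Prüfer enumeration."""
        for m in range(2, 7):
            seqs = [()] if m == 2 else itertools.product(range(m), repeat=m - 2)
            for seq in seqs:
                edges = tree_from_pruefer(list(seq), m)
                got = mst_metrics(nx.Graph(edges))
                exp = brute_tree_metrics(edges, m)
                assert got.max_degree == exp["max_degree"]
                assert got.max_bc == pytest.approx(exp["max_bc"], abs=1e-12)
                assert got.leaf_fraction == pytest.approx(exp["leaf_fraction"])
                assert got.diameter == exp["diameter"]
                assert got.hierarchy == pytest.approx(exp["hierarchy"], abs=1e-12)

    def test_relabeling_invariance(self, rng):
        edges = tree_from_pruefer([2, 0, 3, 1], 6)
        perm = rng.permutation(6)
        relabeled = [(perm[a], perm[b]) for a, b in edges]
        a = mst_metrics(nx.Graph(edges))
        b = mst_metrics(nx.Graph(relabeled))
        assert a == b

    def test_cyclic_input_rejected(self):
        with pytest.raises(ValueError):
            mst_metrics(nx.cycle_graph(5))

    def test_raw_bc_variant(self):
        star = nx.star_graph(4)
        raw = mst_metrics(star, normalized_bc=False)
        assert raw.max_bc == pytest.approx(4 * 3 / 2)


class TestSubjectFeatures:
    def test_feature_vector_shape_and_band_order(self, rng):
        epochs = [EpochSignal(rng.standard_normal((5, 1024)), FS) for _ in range(2)]
        fv = subject_features(epochs, order=2)
        assert fv.shape == (30,)
        assert bn.feature_names()[5] == "theta_max_degree"

    def test_identical_epochs_average_to_single(self, rng):
        epoch = EpochSignal(rng.standard_normal((4, 1024)), FS)
        one = subject_features([epoch], bands={"beta": BANDS["beta"]}, order=2)
        two = subject_features([epoch, epoch], bands={"beta": BANDS["beta"]}, order=2)
        assert one == pytest.approx(two)
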