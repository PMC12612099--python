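"""CRF energy, exact enumeration, mean-field inference, and training."""

import numpy as np
import pytest

from vimloc.core import CRFParams
from vimloc.crf import (
    CRFSubject,
    TrainingConfig,
    build_neighbor_graph,
    energy,
    exact_posterior,
    fit,
    kernel_matrix,
    loss,
    loss_and_gradients,
    mean_field_infer,
    median_heuristic_gamma,
    pairwise_kernel,
    predict,
    unary_cost,
)

from conftest import make_box_grid, make_line_grid


def softmax_rows(z):
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def brute_force_marginals(params, Phi, graph):
    """Second, independently coded enumerator: explicit python loops."""
    V = Phi.shape[0]
    neigh = graph.neighbor_lists()
    weights = {}
    for i, j in graph.edges:
        d2 = float(np.sum((Phi[i] - Phi[j]) ** 2))
        weights[(int(i), int(j))] = np.exp(-params.gamma * d2)
    probs = []
    labelings = []
    for code in range(2**V):
        y = [(code >> v) & 1 for v in range(V)]
        e = sum(float(Phi[i] @ params.W[:, y[i]]) for i in range(V))
        for (i, j), k in weights.items():
            if y[i] != y[j]:
                e += params.rho * k
        probs.append(np.exp(-e))
        labelings.append(y)
    probs = np.array(probs)
    probs /= probs.sum()
    Q = np.zeros((V, 2))
    for p, y in zip(probs, labelings):
        for v in range(V):
            Q[v, y[v]] += p
    return Q


class TestNeighborGraph:
    def test_single_voxel_has_no_neighbours(self):
        g = make_line_grid(1)
        assert build_neighbor_graph(g).n_edges == 0

    def test_two_adjacent_voxels_share_one_edge(self):
        g = make_line_grid(2)
        graph = build_neighbor_graph(g, connectivity=6)
        assert graph.n_edges == 1
        assert graph.neighbor_lists() == [[1], [0]]

    def test_centre_of_full_cube_has_six_face_neighbours(self):
        g = make_box_grid((3, 3, 3))
        graph = build_neighbor_graph(g, connectivity=6)
        centre = int(np.flatnonzero((g.mask_indices == [1, 1, 1]).all(axis=1))[0])
        assert len(graph.neighbor_lists()[centre]) == 6

    @pytest.mark.parametrize("conn, expected", [(6, 6), (18, 18), (26, 26)])
    def test_centre_degree_matches_connectivity(self, conn, expected):
        g = make_box_grid((3, 3, 3))
        graph = build_neighbor_graph(g, connectivity=conn)
        centre = int(np.flatnonzero((g.mask_indices == [1, 1, 1]).all(axis=1))[0])
        assert len(graph.neighbor_lists()[centre]) == expected

    def test_adjacency_is_symmetric_without_self_loops(self):
        g = make_box_grid((3, 2, 2))
        graph = build_neighbor_graph(g)
        adj = graph.neighbor_lists()
        for i, neigh in enumerate(adj):
            assert i not in neigh
            for j in neigh:
                assert i in adj[j]


class TestUnaryAndKernel:
    def test_zero_weights_give_zero_costs(self):
        params = CRFParams(W=np.zeros((4, 2)), rho=0.0, gamma=1.0)
        assert np.allclose(unary_cost(params, np.random.default_rng(0).random((5, 4))), 0)

    def test_one_hot_feature_extracts_weight_entry(self):
        W = np.arange(8.0).reshape(4, 2)
        params = CRFParams(W=W, rho=0.0, gamma=1.0)
        Phi = np.eye(4)[[2]]
        assert np.allclose(unary_cost(params, Phi), W[2])

    def test_matches_loop_based_dot_products(self):
        rng = np.random.default_rng(3)
        Phi = rng.normal(size=(6, 5))
        W = rng.normal(size=(5, 2))
        params = CRFParams(W=W, rho=0.0, gamma=1.0)
        U = unary_cost(params, Phi)
        for i in range(6):
            for k in range(2):
                assert U[i, k] == pytest.approx(float(W[:, k] @ Phi[i]))

    def test_kernel_of_identical_vectors_is_one(self):
        v = np.array([0.3, -1.2, 4.0])
        assert pairwise_kernel(v, v, gamma=2.0) == pytest.approx(1.0)

    def test_kernel_halves_at_log2_squared_distance(self):
        a = np.zeros(1)
        b = np.array([np.sqrt(np.log(2.0))])
        assert pairwise_kernel(a, b, gamma=1.0) == pytest.approx(0.5)

    def test_kernel_is_symmetric(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a, b = rng.normal(size=3), rng.normal(size=3)
            assert pairwise_kernel(a, b, 0.7) == pytest.approx(pairwise_kernel(b, a, 0.7))

    def test_kernel_matrix_matches_pairwise_kernel_on_edges(self):
        g = make_line_grid(4)
        graph = build_neighbor_graph(g)
        rng = np.random.default_rng(5)
        Phi = rng.normal(size=(4, 3))
        K = kernel_matrix(Phi, graph, gamma=0.5)
        for i, j in graph.edges:
            assert K[i, j] == pytest.approx(pairwise_kernel(Phi[i], Phi[j], 0.5))
            assert K[j, i] == pytest.approx(K[i, j])


class TestEnergy:
    def _instance(self, n=3, seed=0):
        g = make_line_grid(n)
        graph = build_neighbor_graph(g)
        rng = np.random.default_rng(seed)
        Phi = rng.normal(size=(n, 3))
        W = rng.normal(size=(3, 2))
        params = CRFParams(W=W, rho=0.4, gamma=0.8)
        return params, Phi, graph

    def test_rho_zero_reduces_to_selected_unary_sum(self):
        params, Phi, graph = self._instance()
        params = CRFParams(W=params.W, rho=0.0, gamma=1.0)
        y = np.array([0, 1, 0])
        U = unary_cost(params, Phi)
        assert energy(params, Phi, y, graph) == pytest.approx(
            U[0, 0] + U[1, 1] + U[2, 0]
        )

    def test_uniform_labels_have_no_pairwise_cost(self):
        params, Phi, graph = self._instance()
        y = np.ones(3, dtype=int)
        U = unary_cost(params, Phi)
        assert energy(params, Phi, y, graph) == pytest.approx(U[:, 1].sum())

    def test_matches_double_loop_oracle_on_chain(self):
        params, Phi, graph = self._instance(seed=7)
        neigh = graph.neighbor_lists()
        for code in range(8):
            y = np.array([(code >> v) & 1 for v in range(3)])
            e = sum(float(Phi[i] @ params.W[:, y[i]]) for i in range(3))
            # oracle: loop over ordered pairs, halve to count each edge once
            pair = 0.0
            for i in range(3):
                for j in neigh[i]:
                    if y[i] != y[j]:
                        pair += params.rho * pairwise_kernel(Phi[i], Phi[j], params.gamma)
            e += pair / 2.0
            assert energy(params, Phi, y, graph) == pytest.approx(e)


class TestExactPosterior:
    def test_single_voxel_zero_weights_is_uniform(self):
        g = make_line_grid(1)
        graph = build_neighbor_graph(g)
        params = CRFParams(W=np.zeros((2, 2)), rho=0.0, gamma=1.0)
        Q = exact_posterior(params, np.ones((1, 2)), graph)
        assert np.allclose(Q, 0.5)

    def test_rho_zero_matches_independent_softmax(self):
        g = make_line_grid(5)
        graph = build_neighbor_graph(g)
        rng = np.random.default_rng(1)
        Phi = rng.normal(size=(5, 3))
        W = rng.normal(size=(3, 2))
        params = CRFParams(W=W, rho=0.0, gamma=1.0)
        assert np.allclose(
            exact_posterior(params, Phi, graph), softmax_rows(-(Phi @ W)), atol=1e-12
        )

    def test_agrees_with_independent_enumerator(self):
        g = make_line_grid(3)
        graph = build_neighbor_graph(g)
        rng = np.random.default_rng(42)
        Phi = rng.normal(size=(3, 2))
        params = CRFParams(W=rng.normal(size=(2, 2)), rho=0.6, gamma=0.9)
        Q = exact_posterior(params, Phi, graph)
        assert np.allclose(Q.sum(axis=1), 1.0)
        assert np.allclose(Q, brute_force_marginals(params, Phi, graph), atol=1e-12)

    def test_refuses_oversized_instances(self):
        g = make_line_grid(16)
        graph = build_neighbor_graph(g)
        params = CRFParams(W=np.zeros((1, 2)), rho=0.0, gamma=1.0)
        with pytest.raises(ValueError, match="refused"):
            exact_posterior(params, np.ones((16, 1)), graph)


class TestMeanField:
    def test_rho_zero_is_exact_in_one_sweep(self):
        g = make_line_grid(6)
        graph = build_neighbor_graph(g)
        rng = np.random.default_rng(2)
        Phi = rng.normal(size=(6, 4))
        params = CRFParams(W=rng.normal(size=(4, 2)), rho=0.0, gamma=1.0)
        Q = mean_field_infer(params, Phi, graph, n_iters=1)
        assert np.allclose(Q, softmax_rows(-(Phi @ params.W)), atol=1e-14)

    def test_zero_weights_and_coupling_give_uniform_marginals(self):
        g = make_line_grid(4)
        graph = build_neighbor_graph(g)
        params = CRFParams(W=np.zeros((3, 2)), rho=0.0, gamma=1.0)
        assert np.allclose(mean_field_infer(params, np.ones((4, 3)), graph), 0.5)

    def test_close_to_enumeration_at_weak_coupling(self):
        worst = 0.0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 11))
            g = make_line_grid(n)
            graph = build_neighbor_graph(g)
            Phi = rng.normal(size=(n, 3))
            params = CRFParams(
                W=rng.normal(size=(3, 2)), rho=float(rng.uniform(0, 0.5)), gamma=1.0
            )
            Q = mean_field_infer(params, Phi, graph, n_iters=50, tol=1e-10)
            tv = 0.5 * np.abs(Q - exact_posterior(params, Phi, graph)).sum(axis=1).max()
            worst = max(worst, tv)
        assert worst <= 0.05

    def test_rejects_non_finite_inputs(self):
        g = make_line_grid(3)
        graph = build_neighbor_graph(g)
        params = CRFParams(W=np.zeros((2, 2)), rho=0.1, gamma=1.0)
        Phi = np.ones((3, 2))
        Phi[1, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            mean_field_infer(params, Phi, graph)


class TestLossAndGradients:
    def _subject(self, n=8, d=3, seed=5):
        g = make_line_grid(n)
        graph = build_neighbor_graph(g)
        rng = np.random.default_rng(seed)
        Phi = rng.normal(size=(n, d))
        T = np.zeros((n, 2))
        T[np.arange(n), rng.integers(0, 2, n)] = 1.0
        return CRFSubject(Phi, graph, T)

    def test_confident_correct_marginals_give_zero_loss(self):
        s = self._subject()
        big = 50.0 * (1 - 2 * s.T[:, [1]])  # low cost (= high margin) for the true class
        Phi = np.c_[big, np.zeros((8, 2))]
        subj = CRFSubject(Phi, s.graph, s.T)
        params = CRFParams(
            W=np.array([[-1.0, 1.0], [0, 0], [0, 0]]), rho=0.0, gamma=1.0
        )
        assert loss(params, [subj]) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_marginals_cost_v_log_two(self):
        s = self._subject(n=10)
        params = CRFParams(W=np.zeros((3, 2)), rho=0.0, gamma=1.0)
        assert loss(params, [s]) == pytest.approx(10 * np.log(2.0))

    def test_l1_penalty_adds_exactly_lambda_times_norm(self):
        s = self._subject()
        W = np.random.default_rng(0).normal(size=(3, 2))
        base = loss(CRFParams(W=W, rho=0.2, gamma=1.0), [s])
        pen = loss(CRFParams(W=W, rho=0.2, gamma=1.0, lambda1=0.7), [s])
        assert pen - base == pytest.approx(0.7 * np.abs(W).sum())

    def test_gradients_match_central_finite_differences(self):
        s = self._subject(n=8, d=3)
        rng = np.random.default_rng(11)
        W = 0.5 * rng.normal(size=(3, 2))
        params = CRFParams(W=W, rho=0.3, gamma=0.7, lambda1=0.01, lambda2=0.02)
        L, dW, drho = loss_and_gradients(params, [s], n_mf_iters=6)
        h = 1e-6

        def f(Wv, rhov):
            p = CRFParams(W=Wv, rho=rhov, gamma=0.7, lambda1=0.01, lambda2=0.02)
            return loss(p, [CRFSubject(s.Phi, s.graph, s.T)], n_mf_iters=6)

        num_dW = np.zeros_like(W)
        for a in range(3):
            for b in range(2):
                Wp, Wm = W.copy(), W.copy()
                Wp[a, b] += h
                Wm[a, b] -= h
                num_dW[a, b] = (f(Wp, 0.3) - f(Wm, 0.3)) / (2 * h)
        num_drho = (f(W, 0.3 + h) - f(W, 0.3 - h)) / (2 * h)
        assert np.abs(dW - num_dW).max() / np.abs(num_dW).max() < 1e-4
        assert abs(drho - num_drho) / abs(num_drho) < 1e-4


class TestFit:
    def _separable_subject(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        g = make_box_grid((10, 10, 3))
        graph = build_neighbor_graph(g)
        Phi = np.c_[rng.normal(size=(n, 3)), np.ones(n)]  # intercept column
        y = (Phi[:, 0] > 0.2).astype(int)
        T = np.zeros((n, 2))
        T[np.arange(n), y] = 1.0
        return CRFSubject(Phi, graph, T), y

    def test_separable_labels_are_learned_to_high_accuracy(self):
        subj, y = self._separable_subject()
        cfg = TrainingConfig(
            rho_init=0.0, lambda1=0.0, lambda2=0.0, n_epochs=150,
            learning_rate=1.0, lr_decay=1.0, seed=1, gamma=1.0,
        )
        params, trace = fit([subj], cfg)
        acc = ((-(subj.Phi @ params.W)).argmax(axis=1) == y).mean()
        assert acc >= 0.99
        assert trace[-1] < trace[0]

    def test_same_seed_gives_identical_fits(self):
        subj, _ = self._separable_subject()
        cfg = TrainingConfig(n_epochs=5, seed=3, gamma=1.0)
        p1, t1 = fit([subj], cfg)
        p2, t2 = fit([subj], cfg)
        assert np.array_equal(p1.W, p2.W)
        assert p1.rho == p2.rho and t1 == t2

    def test_huge_ridge_penalty_crushes_the_weights(self):
        subj, _ = self._separable_subject()
        cfg = TrainingConfig(
            rho_init=0.0, lambda1=0.0, lambda2=1e4, n_epochs=60, seed=0, gamma=1.0
        )
        params, _ = fit([subj], cfg)
        assert np.abs(params.W).max() < 1e-2

    def test_non_finite_loss_is_reported_with_epoch_and_rate(self):
        """Corrupt features must surface as a named training error, not as
        silently non-finite parameters."""
        subj, _ = self._separable_subject()
        subj.Phi[0, 0] = np.inf
        cfg = TrainingConfig(rho_init=0.0, n_epochs=5, seed=0, gamma=1.0)
        with pytest.raises(FloatingPointError, match="epoch"):
            fit([subj], cfg)

    def test_median_heuristic_sets_median_edge_kernel_to_half(self):
        g = make_box_grid((4, 4, 4))
        graph = build_neighbor_graph(g)
        Phi = np.random.default_rng(0).normal(size=(g.n_voxels, 5))
        gamma = median_heuristic_gamma(Phi, graph)
        i, j = graph.edges.T
        d2 = np.sum((Phi[i] - Phi[j]) ** 2, axis=1)
        assert np.median(np.exp(-gamma * d2)) == pytest.approx(0.5, abs=1e-4)


class TestPredict:
    def test_prediction_is_deterministic(self):
        g = make_box_grid((4, 4, 4))
        graph = build_neighbor_graph(g)
        rng = np.random.default_rng(8)
        Phi = rng.normal(size=(g.n_voxels, 3))
        params = CRFParams(W=rng.normal(size=(3, 2)), rho=0.2, gamma=0.5)
        a = predict(params, Phi, graph)
        b = predict(params, Phi, graph)
        assert np.array_equal(a.Q, b.Q)

    def test_rows_sum_to_one(self):
        g = make_box_grid((3, 3, 3))
        graph = build_neighbor_graph(g)
        rng = np.random.default_rng(9)
        Phi = rng.normal(size=(g.n_voxels, 4))
        params = CRFParams(W=rng.normal(size=(4, 2)), rho=0.5, gamma=0.3)
        field = predict(params, Phi, graph)
        assert np.allclose(field.Q.sum(axis=1), 1.0, atol=1e-9)

    def test_separable_fit_reproduces_labels_at_prediction_time(self):
        rng = np.random.default_rng(0)
        g = make_box_grid((10, 10, 3))
        graph = build_neighbor_graph(g)
        Phi = np.c_[rng.normal(size=(300, 3)), np.ones(300)]
        y = (Phi[:, 0] > 0.2).astype(int)
        T = np.zeros((300, 2))
        T[np.arange(300), y] = 1.0
        cfg = TrainingConfig(
            rho_init=0.0, lambda1=0.0, lambda2=0.0, n_epochs=150,
            learning_rate=1.0, lr_decay=1.0, seed=1, gamma=1.0,
        )
        params, _ = fit([CRFSubject(Phi, graph, T)], cfg)
        field = predict(params, Phi, graph)
        assert (field.Q.argmax(axis=1) == y).mean() >= 0.99
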