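import numpy as np
import pytest

from conftest import random_instance
from oracles import (finite_diff_grad, grid_search_location,
                     grid_search_proportion)

from geomix.em import m_step_locations, m_step_proportions, q_location, run_em
from geomix.hmm import TransitionModel, build_transition, forward_backward
from geomix.simulate import make_synthetic_gradients, simulate_admixed_haplotype
from geomix.evaluate import prediction_errors

EXTENT = ((0.0, 10.0), (0.0, 10.0))


class TestMStepLocations:
    def test_single_ancestry_matches_grid_search(self):
        h, grad, model, _ = random_instance(seed=1, L=60, M=1, steepness=0.8)
        h = h.astype(np.int8)
        C = np.ones((60, 1))
        X = m_step_locations(C, h, grad, np.array([[5.0, 5.0]]))
        x_grid, _ = grid_search_location(C[:, 0], h, grad, EXTENT, step=0.05)
        assert np.all(np.abs(X[0] - x_grid) <= 0.05)

    def test_weighted_two_ancestry_subproblems_match_grid_search(self):
        rng = np.random.default_rng(2)
        grad = make_synthetic_gradients(80, EXTENT, steepness=0.8, seed=2)
        truth = np.array([[2.0, 3.0], [8.0, 7.0]])
        z = rng.integers(0, 2, 80)
        F = grad.frequencies(truth)
        h = (rng.random(80) < F[np.arange(80), z]).astype(np.int8)
        C = np.zeros((80, 2))
        C[np.arange(80), z] = 1.0  # true ancestry indicators
        X = m_step_locations(C, h, grad, np.array([[5.0, 5.0], [5.0, 5.0]]))
        for j in range(2):
            x_grid, _ = grid_search_location(C[:, j], h, grad, EXTENT, step=0.05)
            assert np.all(np.abs(X[j] - x_grid) <= 0.10)  # within 2 grid cells

    def test_flat_gradients_leave_locations_unchanged(self):
        h, grad, model, _ = random_instance(seed=3, L=20, M=2)
        grad.a[:] = 0.0
        X0 = model.X.copy()
        X = m_step_locations(np.full((20, 2), 0.5), h, grad, X0)
        np.testing.assert_allclose(X, X0)

    def test_zero_weight_column_warns_and_keeps_location(self):
        h, grad, model, _ = random_instance(seed=4, L=20, M=2)
        C = np.zeros((20, 2))
        C[:, 0] = 1.0
        with pytest.warns(RuntimeWarning, match="no posterior weight"):
            X = m_step_locations(C, h, grad, model.X)
        np.testing.assert_allclose(X[1], model.X[1])

    def test_objective_never_decreases(self):
        for seed in range(10):
            h, grad, model, trans = random_instance(seed=seed, L=40, M=2)
            post = forward_backward(h, grad, model, trans)
            X = m_step_locations(post.C, h, grad, model.X)
            h8 = h.astype(np.int8)
            idx = np.flatnonzero(h8 >= 0)
            for j in range(2):
                q0 = q_location(model.X[j], post.C[idx, j], h8[idx].astype(float), grad, idx)
                q1 = q_location(X[j], post.C[idx, j], h8[idx].astype(float), grad, idx)
                assert q1 >= q0 - 1e-10

    def test_analytic_gradient_matches_finite_differences(self):
        h, grad, model, trans = random_instance(seed=5, L=50, M=2, steepness=0.8)
        post = forward_backward(h, grad, model, trans)
        h8 = h.astype(np.int8)
        idx = np.flatnonzero(h8 >= 0)
        w = post.C[idx, 0]
        hh = h8[idx].astype(float)
        A, b = grad.a[idx], grad.b[idx]
        from scipy.special import expit

        def f(x):
            return q_location(x, w, hh, grad, idx)

        x0 = np.array([4.1, 6.3])
        p = expit(A @ x0 + b)
        analytic = A.T @ (w * (hh - p))
        numeric = finite_diff_grad(f, x0)
        assert np.max(np.abs(analytic - numeric)) / max(1.0, np.max(np.abs(numeric))) < 1e-6


class TestMStepProportions:
    def test_single_ancestry_trivial(self):
        assert m_step_proportions(np.ones((5, 1)), np.ones((4, 1)),
                                  TransitionModel(tau=np.full(4, 0.3))) == pytest.approx([1.0])

    def test_full_switching_reduces_to_normalized_counts(self):
        rng = np.random.default_rng(6)
        D = rng.random((10, 3))
        E = rng.random((9, 3))
        pi = m_step_proportions(D, E, TransitionModel(tau=np.ones(9)))
        tot = D.sum(axis=0) + E.sum(axis=0)
        np.testing.assert_allclose(pi, tot / tot.sum(), rtol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_one_dimensional_grid_search(self, seed):
        h, grad, model, trans = random_instance(seed=seed + 70, L=6, M=2)
        post = forward_backward(h, grad, model, trans)
        pi = m_step_proportions(post.D, post.E, trans)
        pi_grid, _ = grid_search_proportion(post.D, post.E, trans.tau, step=1e-4)
        assert abs(pi[0] - pi_grid[0]) <= 2e-4

    def test_degenerate_counts_return_uniform(self):
        pi = m_step_proportions(np.zeros((5, 3)), np.zeros((4, 3)),
                                TransitionModel(tau=np.full(4, 0.2)))
        np.testing.assert_allclose(pi, 1 / 3)


class TestRunEM:
    def test_recovers_single_ancestor_location(self):
        grad = make_synthetic_gradients(5000, ((0, 20), (0, 20)), steepness=2.0, seed=7)
        truth = np.array([[5.0, 12.0]])
        h, _ = simulate_admixed_haplotype(grad, 4, ancestor_locations=truth, seed=11)
        trans = build_transition(grad, 4)
        res = run_em(h, grad, 1, trans, restarts=3, seed=0)
        assert np.hypot(*(res.model.X[0] - truth[0])) < 0.1

    def test_flat_gradients_converge_immediately(self):
        grad = make_synthetic_gradients(30, seed=8, informative_fraction=0.0)
        grad.a[:] = 0.0
        rng = np.random.default_rng(8)
        h = rng.integers(0, 2, 30)
        trans = build_transition(grad, 4)
        res = run_em(h, grad, 2, trans, restarts=3, seed=1)
        assert res.n_iter <= 2
        # every restart reaches the identical (location-independent) likelihood
        res2 = run_em(h, grad, 2, trans, restarts=1, seed=99)
        assert res.loglik == pytest.approx(res2.loglik, rel=1e-12)

    def test_two_ancestor_recovery_and_consistency_in_L(self):
        """Error < 10% of separation at L=20000; median error shrinks with L."""
        sep_truth = np.array([[5.0, 15.0], [25.0, 15.0]])  # 20 map units apart
        medians = []
        for L in (1000, 5000, 20000):
            errs = []
            for rep in range(3):
                grad = make_synthetic_gradients(L, ((0, 30), (0, 30)), steepness=2.0,
                                                seed=500 + 10 * rep + L % 97,
                                                spacing_bp=max(20_000, 400_000_000 // L))
                h, _ = simulate_admixed_haplotype(grad, 4, ancestor_locations=sep_truth,
                                                  seed=600 + rep)
                trans = build_transition(grad, 4)
                res = run_em(h, grad, 2, trans, restarts=3, seed=rep)
                pe, _ = prediction_errors(res.model.X, sep_truth)
                errs.append(pe)
            medians.append(np.median(errs))
        assert medians[-1] < 0.1 * 20.0
        assert medians[0] > medians[1] > medians[2]

    def test_loglik_trace_never_decreases(self):
        for seed in range(15):
            h, grad, model, trans = random_instance(seed=seed + 200, L=40, M=2)
            res = run_em(h, grad, 2, trans, restarts=1, seed=seed, max_iter=30)
            assert np.all(np.diff(res.loglik_trace) >= -1e-8)

    def test_label_symmetry_under_matching(self):
        """Different initializations permute labels; matched metrics agree."""
        grad = make_synthetic_gradients(2000, ((0, 30), (0, 30)), steepness=2.0,
                                        seed=9, spacing_bp=200_000)
        truth = np.array([[8.0, 10.0], [22.0, 20.0]])
        h, _ = simulate_admixed_haplotype(grad, 4, ancestor_locations=truth, seed=10)
        trans = build_transition(grad, 4)
        r1 = run_em(h, grad, 2, trans, restarts=1, seed=1)
        r2 = run_em(h, grad, 2, trans, restarts=1, seed=5)
        pe1, _ = prediction_errors(r1.model.X, truth)
        pe2, _ = prediction_errors(r2.model.X, truth)
        assert pe1 == pytest.approx(pe2, abs=0.2)

    def test_too_many_ancestries_rejected(self):
        h, grad, model, trans = random_instance(seed=11, L=5, M=2)
        with pytest.raises(ValueError):
            run_em(h, grad, 6, trans)
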