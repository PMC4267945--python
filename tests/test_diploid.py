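import numpy as np
import pytest

from oracles import enumerate_diploid, finite_diff_grad, grid_search_location

from geomix.diploid import (DiploidAncestryModel, diploid_emission,
                            diploid_emission_matrix, diploid_forward_backward,
                            diploid_loglikelihood, diploid_m_step_locations,
                            diploid_viterbi, run_em_diploid, _q_objective,
                            _clean_genotype)
from geomix.hmm import TransitionModel, build_transition
from geomix.simulate import (SimConfig, make_synthetic_gradients,
                             simulate_admixed_genotype, simulate_admixed_haplotype)

EXTENT = ((0.0, 10.0), (0.0, 10.0))


def random_diploid_instance(seed, L=6, M=2, N=2, steepness=0.5):
    rng = np.random.default_rng(seed)
    grad = make_synthetic_gradients(L, EXTENT, steepness=steepness, seed=seed)
    g = rng.integers(0, 3, L).astype(float)
    model = DiploidAncestryModel(
        X=rng.uniform(0, 10, (M, 2)), Y=rng.uniform(0, 10, (N, 2)),
        Pi=rng.dirichlet(np.ones(M)), Omega=rng.dirichlet(np.ones(N)))
    trans = TransitionModel(tau=rng.uniform(0, 1, L - 1))
    return g, grad, model, trans


class TestEmission:
    def test_heterozygote_at_half_half(self):
        assert diploid_emission(1, 0.5, 0.5) == pytest.approx(0.5)

    def test_homozygote_product(self):
        assert diploid_emission(2, 0.9, 0.2) == pytest.approx(0.18)

    def test_total_probability_is_one(self, rng):
        for _ in range(20):
            fx, fy = rng.uniform(0.01, 0.99, 2)
            assert sum(diploid_emission(g, fx, fy) for g in (0, 1, 2)) == pytest.approx(1.0)

    def test_missing_contributes_one(self):
        assert diploid_emission(None, 0.3, 0.7) == 1.0
        assert diploid_emission(np.nan, 0.3, 0.7) == 1.0

    def test_invalid_genotype_rejected(self):
        with pytest.raises(ValueError):
            diploid_emission(3, 0.5, 0.5)
        with pytest.raises(ValueError):
            _clean_genotype(np.array([0.0, 4.0]), 2)


class TestForwardBackward:
    def test_single_joint_state_closed_form(self):
        g, grad, _, trans = random_diploid_instance(seed=1, M=1, N=1, L=8)
        model = DiploidAncestryModel(X=[[2.0, 3.0]], Y=[[7.0, 5.0]])
        E = diploid_emission_matrix(g, grad, model.X, model.Y)
        expected = float(np.log(E[:, 0, 0]).sum())
        assert diploid_loglikelihood(g, grad, model, trans) == pytest.approx(expected)
        post = diploid_forward_backward(g, grad, model, trans)
        assert post.loglik == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        g, grad, model, trans = random_diploid_instance(seed=seed + 10)
        ll, C, _ = enumerate_diploid(g, grad, model, trans)
        post = diploid_forward_backward(g, grad, model, trans)
        assert post.loglik == pytest.approx(ll, rel=1e-10)
        np.testing.assert_allclose(post.C, C, atol=1e-10)

    def test_symmetric_chains_give_exchangeable_posteriors(self):
        g, grad, _, trans = random_diploid_instance(seed=30)
        rng = np.random.default_rng(30)
        X = rng.uniform(0, 10, (2, 2))
        model = DiploidAncestryModel(X=X, Y=X.copy())
        post = diploid_forward_backward(g, grad, model, trans)
        np.testing.assert_allclose(post.C, np.swapaxes(post.C, 1, 2), atol=1e-9)

    def test_locus_slices_normalize_and_marginals_match(self):
        g, grad, model, trans = random_diploid_instance(seed=31, L=12)
        post = diploid_forward_backward(g, grad, model, trans)
        np.testing.assert_allclose(post.C.sum(axis=(1, 2)), 1.0, atol=1e-9)
        np.testing.assert_allclose(post.paternal, post.C.sum(axis=2), atol=1e-12)
        np.testing.assert_allclose(post.maternal, post.C.sum(axis=1), atol=1e-12)

    def test_chain_counts_consistent_with_marginals(self):
        g, grad, model, trans = random_diploid_instance(seed=32, L=10)
        post = diploid_forward_backward(g, grad, model, trans)
        np.testing.assert_allclose(post.D_p[1:] + post.E_p, post.paternal[1:], atol=1e-9)
        np.testing.assert_allclose(post.D_m[1:] + post.E_m, post.maternal[1:], atol=1e-9)


class TestMStepLocations:
    def test_homozygous_only_separates_into_independent_problems(self):
        rng = np.random.default_rng(3)
        grad = make_synthetic_gradients(50, EXTENT, steepness=0.8, seed=3)
        g = rng.choice([0.0, 2.0], 50)
        C = rng.dirichlet(np.ones(4), size=50).reshape(50, 2, 2)
        X0 = np.array([[5.0, 5.0], [5.0, 5.0]])
        Y0 = np.array([[5.0, 5.0], [5.0, 5.0]])
        X, Y = diploid_m_step_locations(C, g, grad, X0, Y0)
        # independent per-chain solutions from the haploid Newton machinery
        from geomix.em import m_step_locations
        h_equiv = (g / 2).astype(np.int8)  # 0 -> 0, 2 -> 1
        Xi = m_step_locations(C.sum(axis=2), h_equiv, grad, X0)
        Yi = m_step_locations(C.sum(axis=1), h_equiv, grad, Y0)
        np.testing.assert_allclose(X, Xi, atol=1e-5)
        np.testing.assert_allclose(Y, Yi, atol=1e-5)

    def test_flat_gradients_keep_initial_locations(self):
        g, grad, model, _ = random_diploid_instance(seed=4, L=20)
        grad.a[:] = 0.0
        C = np.full((20, 2, 2), 0.25)
        X, Y = diploid_m_step_locations(C, g, grad, model.X, model.Y)
        np.testing.assert_allclose(X, model.X, atol=1e-6)
        np.testing.assert_allclose(Y, model.Y, atol=1e-6)

    def test_single_pair_matches_grid_search(self):
        rng = np.random.default_rng(5)
        grad = make_synthetic_gradients(50, EXTENT, steepness=0.8, seed=5)
        truth = SimConfig(L=50, generations=1, ancestor_locations=np.array([[3.0, 4.0]]),
                          maternal_locations=np.array([[7.0, 6.0]]), seed=6)
        g, _, _ = simulate_admixed_genotype(truth, grad)
        C = np.ones((50, 1, 1))
        # asymmetric start: a symmetric X = Y initialization is a fixed point
        # of the coupled heterozygote term and cannot separate the parents
        X, Y = diploid_m_step_locations(C, g, grad, np.array([[4.0, 4.0]]),
                                        np.array([[6.0, 6.0]]))
        # compare against a 4-D grid via the homozygous separation trick is not
        # exact here; instead verify the objective beats every coarse grid point
        theta = np.concatenate([X.ravel(), Y.ravel()])
        g8 = _clean_genotype(g, 50)
        f_opt, _ = _q_objective(theta, C, g8, grad, 1, 1, False)
        grid = np.arange(0.0, 10.01, 0.5)
        for ux in grid[::2]:
            for vx in grid[::2]:
                for uy in grid[::2]:
                    for vy in grid[::2]:
                        f, _ = _q_objective(np.array([ux, vx, uy, vy]), C, g8,
                                            grad, 1, 1, False)
                        assert f_opt <= f + 1e-9

    def test_analytic_gradient_matches_finite_differences(self):
        g, grad, model, trans = random_diploid_instance(seed=7, L=40, steepness=0.8)
        post = diploid_forward_backward(g, grad, model, trans)
        g8 = _clean_genotype(g, 40)
        theta0 = np.concatenate([model.X.ravel(), model.Y.ravel()])

        def f(th):
            return _q_objective(th, post.C, g8, grad, 2, 2, False)[0]

        _, analytic = _q_objective(theta0, post.C, g8, grad, 2, 2, False)
        numeric = finite_diff_grad(f, theta0)
        rel = np.max(np.abs(analytic - numeric)) / max(1.0, np.max(np.abs(numeric)))
        assert rel < 1e-6


class TestViterbiDecoding:
    def test_single_joint_state_constant_path(self):
        g, grad, _, trans = random_diploid_instance(seed=8, M=1, N=1, L=8)
        model = DiploidAncestryModel(X=[[2.0, 3.0]], Y=[[7.0, 5.0]])
        pat, mat = diploid_viterbi(g, grad, model, trans)
        assert np.all(pat == 0) and np.all(mat == 0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumerated_argmax(self, seed):
        g, grad, model, trans = random_diploid_instance(seed=seed + 40)
        *_, best = enumerate_diploid(g, grad, model, trans)
        pat, mat = diploid_viterbi(g, grad, model, trans)
        assert tuple(pat) == best[0] and tuple(mat) == best[1]

    def test_symmetric_ties_resolve_lexicographically(self):
        g, grad, _, trans = random_diploid_instance(seed=9)
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 10, (2, 2))
        model = DiploidAncestryModel(X=X, Y=X.copy())
        pat1, mat1 = diploid_viterbi(g, grad, model, trans)
        pat2, mat2 = diploid_viterbi(g, grad, model, trans)
        np.testing.assert_array_equal(pat1, pat2)
        np.testing.assert_array_equal(mat1, mat2)


class TestRunEMDiploid:
    def test_recovers_two_parent_locations(self):
        grad = make_synthetic_gradients(5000, ((0, 20), (0, 20)), steepness=2.0, seed=9)
        cfg = SimConfig(L=5000, generations=1, ancestor_locations=np.array([[4.0, 6.0]]),
                        maternal_locations=np.array([[16.0, 14.0]]), seed=10)
        geno, _, _ = simulate_admixed_genotype(cfg, grad)
        trans = build_transition(grad, 1)
        res = run_em_diploid(geno, grad, 1, 1, trans, restarts=3, seed=1)
        truth = np.array([[4.0, 6.0], [16.0, 14.0]])
        found = np.vstack([res.model.X, res.model.Y])
        # permutation-matched since M = N = 1 leaves a paternal/maternal swap
        d_direct = np.hypot(*(found - truth).T)
        d_swap = np.hypot(*(found[::-1] - truth).T)
        assert min(d_direct.mean(), d_swap.mean()) < 0.15

    def test_homogeneous_constraint_enforced(self):
        grad = make_synthetic_gradients(600, ((0, 20), (0, 20)), steepness=1.5,
                                        seed=11, spacing_bp=500_000)
        cfg = SimConfig(L=600, generations=4, homogeneous=True,
                        ancestor_locations=np.array([[5.0, 10.0], [15.0, 10.0]]),
                        seed=12)
        geno, _, _ = simulate_admixed_genotype(cfg, grad)
        trans = build_transition(grad, 4)
        res = run_em_diploid(geno, grad, 2, 2, trans, homogeneous=True,
                             restarts=2, seed=2, max_iter=50)
        np.testing.assert_array_equal(res.model.X, res.model.Y)

    def test_loglik_trace_never_decreases(self):
        for seed in range(8):
            g, grad, model, trans = random_diploid_instance(seed=seed + 300, L=30)
            res = run_em_diploid(g, grad, 2, 2, trans, restarts=1, seed=seed,
                                 max_iter=15)
            assert np.all(np.diff(res.loglik_trace) >= -1e-8)

    def test_paternal_marginals_track_haploid_model(self):
        """One admixed + one constant-ancestry haplotype: the diploid paternal
        posteriors should correlate strongly with the haploid decoding of the
        admixed haplotype when the second parent sits at a known location."""
        grad = make_synthetic_gradients(2000, ((0, 20), (0, 20)), steepness=2.0,
                                        seed=13, spacing_bp=200_000)
        X_true = np.array([[4.0, 4.0], [16.0, 16.0]])
        mom = np.array([[10.0, 10.0]])
        hp, truth = simulate_admixed_haplotype(grad, 4, ancestor_locations=X_true, seed=14)
        hm, _ = simulate_admixed_haplotype(grad, 1, ancestor_locations=mom, seed=15)
        geno = hp + hm
        trans = build_transition(grad, 4)
        from geomix.hmm import AncestryModel, forward_backward
        hap_post = forward_backward(hp, grad, AncestryModel(X=X_true), trans)
        dip_post = diploid_forward_backward(
            geno, grad, DiploidAncestryModel(X=X_true, Y=mom), trans)
        r = np.corrcoef(hap_post.C[:, 0], dip_post.paternal[:, 0])[0, 1]
        assert r > 0.95
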