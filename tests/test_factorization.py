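"""Objective, multiplicative updates, KKT residuals, reconstruction metric."""

import numpy as np
import pytest

from atvnetnmf.containers import NetworkTriple
from atvnetnmf.factorization import (
    ATVNetNMF,
    factorize,
    initialize_factors,
    kkt_residual,
    objective,
    objective_gradients,
    reconstruction_correlation,
    update_step,
    variant_flags,
)
from atvnetnmf.networks import build_graph_laplacian, build_network_triple
from atvnetnmf.synthetic import generate_planted_multiomics, random_network_triple
from atvnetnmf.tv import forward_gradient, tv_divergence


def netnmf_reference_run(R11, R12, R22, G1, G2, S11, S22, alpha, beta, n_steps,
                         floor=1e-12):
    """Independently coded plain netNMF multiplicative updates (no graph, no TV).

    Serves as the reduction oracle: with the regularizers switched off the
    full model must reproduce these trajectories exactly.
    """
    G1, G2, S11, S22 = G1.copy(), G2.copy(), S11.copy(), S22.copy()
    for _ in range(n_steps):
        S11 = S11 * ((G1.T @ R11 @ G1) /
                     np.maximum(G1.T @ G1 @ S11 @ (G1.T @ G1), floor))
        S22 = S22 * ((G2.T @ R22 @ G2) /
                     np.maximum(G2.T @ G2 @ S22 @ (G2.T @ G2), floor))
        num = alpha * (R12 @ G2) + 2.0 * (R11 @ G1 @ S11)
        den = 2.0 * (G1 @ (S11 @ (G1.T @ G1) @ S11)) + alpha * (G1 @ (G2.T @ G2))
        G1 = G1 * (num / np.maximum(den, floor))
        num = alpha * (R12.T @ G1) + 2.0 * beta * (R22 @ G2 @ S22)
        den = 2.0 * beta * (G2 @ (S22 @ (G2.T @ G2) @ S22)) + alpha * (G2 @ (G1.T @ G1))
        G2 = G2 * (num / np.maximum(den, floor))
    return G1, G2, S11, S22


def exact_instance(n1=12, n2=9, k=3, seed=0):
    """Zero-residual instance: networks built from known non-negative factors."""
    rng = np.random.default_rng(seed)
    G1 = rng.uniform(0.1, 1.0, size=(n1, k))
    G2 = rng.uniform(0.1, 1.0, size=(n2, k))
    A1 = rng.uniform(0.1, 1.0, size=(k, k))
    A2 = rng.uniform(0.1, 1.0, size=(k, k))
    S11 = A1.T @ A1
    S22 = A2.T @ A2
    R11 = G1 @ S11 @ G1.T
    R12 = G1 @ G2.T
    R22 = G2 @ S22 @ G2.T
    return R11, R12, R22, G1, G2, S11, S22


class TestObjective:
    def test_zero_factors_gives_sum_of_squared_norms(self, small_nets):
        n1, n2, k = small_nets.n1, small_nets.n2, 4
        zeros = [np.zeros((n1, k)), np.zeros((n2, k)), np.zeros((k, k)),
                 np.zeros((k, k))]
        val = objective(small_nets.R11, small_nets.R12, small_nets.R22, *zeros,
                        alpha=0.7, beta=1.3)
        expected = (np.sum(small_nets.R11 ** 2) + 0.7 * np.sum(small_nets.R12 ** 2)
                    + 1.3 * np.sum(small_nets.R22 ** 2))
        assert val == pytest.approx(expected, rel=1e-12)

    def test_exact_factorization_gives_zero(self):
        R11, R12, R22, G1, G2, S11, S22 = exact_instance()
        val = objective(R11, R12, R22, G1, G2, S11, S22, alpha=1.0, beta=1.0)
        assert val == pytest.approx(0.0, abs=1e-10)

    def test_matches_term_by_term_oracle(self, rng):
        R11, R12, R22, G1, G2, S11, S22 = exact_instance(seed=5)
        G1 = G1 + rng.uniform(0, 0.2, G1.shape)
        G2 = G2 + rng.uniform(0, 0.2, G2.shape)
        L1 = build_graph_laplacian(R11, 3)
        L2 = build_graph_laplacian(R22, 3)
        alpha, beta, lam1, lam2, eps = 0.9, 1.4, 0.05, 0.07, 1e-8
        val = objective(R11, R12, R22, G1, G2, S11, S22, alpha=alpha, beta=beta,
                        lambda1=lam1, lambda2=lam2, L1=L1, L2=L2, tv=True,
                        grad_epsilon=eps)
        # every term recomputed independently, entrywise
        expected = np.sum((R11 - G1 @ S11 @ G1.T) ** 2)
        expected += alpha * np.sum((R12 - G1 @ G2.T) ** 2)
        expected += beta * np.sum((R22 - G2 @ S22 @ G2.T) ** 2)
        for lam, L, G in ((lam1, L1, G1), (lam2, L2, G2)):
            expected += lam * sum(
                G[:, j] @ L.L @ G[:, j] for j in range(G.shape[1])
            )
            gx, gy = forward_gradient(G)
            m = np.sqrt(gx ** 2 + gy ** 2 + eps ** 2)
            p = 1.0 + 1.0 / (1.0 + gx ** 2 + gy ** 2)
            expected += 2.0 * np.sum(m ** p / p)
        assert val == pytest.approx(expected, rel=1e-12)

    def test_scale_homogeneity(self, small_nets):
        # scaling networks by c and loadings by sqrt(c) scales the
        # constraint-off objective by c^2 (residual homogeneity)
        G1, G2, S11, S22 = initialize_factors(small_nets.n1, small_nets.n2, 3, 0)
        c = 3.7
        base = objective(small_nets.R11, small_nets.R12, small_nets.R22,
                         G1, G2, S11, S22, alpha=0.8, beta=0.64)
        scaled = objective(c * small_nets.R11, c * small_nets.R12,
                           c * small_nets.R22, np.sqrt(c) * G1, np.sqrt(c) * G2,
                           S11, S22, alpha=0.8, beta=0.64)
        assert scaled == pytest.approx(c ** 2 * base, rel=1e-10)

    def test_shape_mismatch_names_operand(self, small_nets):
        G1, G2, S11, S22 = initialize_factors(small_nets.n1, small_nets.n2, 3, 0)
        with pytest.raises(ValueError, match="G2"):
            objective(small_nets.R11, small_nets.R12, small_nets.R22,
                      G1, G2[:-1], S11, S22, alpha=1.0, beta=1.0)


class TestUpdateStep:
    def test_exact_factorization_is_fixed_point(self):
        R11, R12, R22, G1, G2, S11, S22 = exact_instance()
        out = update_step(R11, R12, R22, G1, G2, S11, S22, alpha=1.0, beta=1.0)
        for new, old in zip(out, (G1, G2, S11, S22)):
            assert np.max(np.abs(new - old)) < 1e-10

    def test_reduces_exactly_to_netnmf_reference(self, small_nets):
        G1, G2, S11, S22 = initialize_factors(small_nets.n1, small_nets.n2, 4,
                                              random_state=11)
        alpha, beta = 0.8, 0.64
        ref = netnmf_reference_run(small_nets.R11, small_nets.R12, small_nets.R22,
                                   G1, G2, S11, S22, alpha, beta, n_steps=50)
        ours = (G1.copy(), G2.copy(), S11.copy(), S22.copy())
        for _ in range(50):
            ours = update_step(small_nets.R11, small_nets.R12, small_nets.R22,
                               *ours, alpha=alpha, beta=beta, tv=False)
        for a, b in zip(ours, ref):
            np.testing.assert_array_equal(a, b)

    def test_netnmf_mode_monotone_50_steps(self):
        nets = random_network_triple(30, 20, n_samples=25, seed=2)
        G1, G2, S11, S22 = initialize_factors(30, 20, 8, random_state=2)
        alpha, beta = 1.5, 2.25
        prev = objective(nets.R11, nets.R12, nets.R22, G1, G2, S11, S22,
                         alpha=alpha, beta=beta)
        state = (G1, G2, S11, S22)
        for _ in range(50):
            state = update_step(nets.R11, nets.R12, nets.R22, *state,
                                alpha=alpha, beta=beta, tv=False)
            cur = objective(nets.R11, nets.R12, nets.R22, *state,
                            alpha=alpha, beta=beta)
            assert cur <= prev * (1 + 1e-9)
            prev = cur

    @pytest.mark.parametrize("variant", ["netnmf", "nmfna", "netnmf-atv",
                                         "atv-netnmf"])
    def test_nonnegativity_all_variants(self, variant, rng):
        graph, tv = variant_flags(variant)
        for seed in range(5):
            nets = random_network_triple(14, 11, n_samples=12, seed=100 + seed)
            L1 = build_graph_laplacian(nets.R11, 3) if graph else None
            L2 = build_graph_laplacian(nets.R22, 3) if graph else None
            state = initialize_factors(14, 11, 3, random_state=seed)
            for _ in range(20):
                state = update_step(nets.R11, nets.R12, nets.R22, *state,
                                    alpha=14 / 11, beta=(14 / 11) ** 2,
                                    lambda1=0.08, lambda2=0.08, L1=L1, L2=L2,
                                    tv=tv)
                for F in state:
                    assert np.all(F >= 0) and np.all(np.isfinite(F))


class TestATVNetNMFEstimator:
    def test_determinism_same_seed(self, small_nets):
        a = ATVNetNMF(n_components=3, max_iter=30, random_state=42).fit(small_nets)
        b = ATVNetNMF(n_components=3, max_iter=30, random_state=42).fit(small_nets)
        np.testing.assert_array_equal(a.G1_, b.G1_)
        np.testing.assert_array_equal(a.G2_, b.G2_)
        np.testing.assert_array_equal(a.S11_, b.S11_)
        np.testing.assert_array_equal(a.S22_, b.S22_)
        assert a.objective_trace_ == b.objective_trace_

    def test_trace_length_and_tolerance_stop(self, small_nets):
        m = ATVNetNMF(n_components=3, max_iter=300, tol=1e-6, graph=False,
                      tv=False, random_state=0).fit(small_nets)
        assert m.n_iter_ <= 300
        assert len(m.objective_trace_) == m.n_iter_

    def test_planted_data_objective_halves(self):
        X1, X2, truth = generate_planted_multiomics(n1=80, n2=100, n_samples=40,
                                                    k_true=4, seed=1)
        nets = build_network_triple(X1, X2)
        m = ATVNetNMF(n_components=4, graph=False, tv=False,
                      random_state=1).fit(nets)
        assert m.objective_trace_[-1] < 0.5 * m.initial_objective_

    def test_final_objective_not_worse_all_variants(self):
        for variant in ("netnmf", "nmfna", "netnmf-atv", "atv-netnmf"):
            for seed in range(3):
                nets = random_network_triple(16, 13, n_samples=12, seed=7 + seed)
                m = ATVNetNMF.from_variant(variant, n_components=3, max_iter=60,
                                           n_neighbors=3,
                                           random_state=seed).fit(nets)
                assert m.objective_trace_[-1] <= m.initial_objective_

    def test_symmetry_preserved_200_iterations(self, small_nets):
        m = ATVNetNMF(n_components=4, max_iter=200, n_neighbors=3,
                      random_state=5).fit(small_nets)
        assert np.max(np.abs(m.S11_ - m.S11_.T)) < 1e-8
        assert np.max(np.abs(m.S22_ - m.S22_.T)) < 1e-8

    def test_auto_weight_resolution(self, small_nets):
        m = ATVNetNMF(n_components=2, max_iter=2, random_state=0).fit(small_nets)
        assert m.alpha_ == pytest.approx(small_nets.n1 / small_nets.n2)
        assert m.beta_ == pytest.approx((small_nets.n1 / small_nets.n2) ** 2)

    def test_k_out_of_range_rejected(self, small_nets):
        with pytest.raises(ValueError, match="n_components"):
            ATVNetNMF(n_components=50).fit(small_nets)

    def test_sklearn_param_interface(self):
        m = ATVNetNMF(n_components=5)
        assert m.get_params()["n_components"] == 5
        m.set_params(lambda1=0.02)
        assert m.lambda1 == 0.02

    def test_factorize_wrapper_matches_estimator(self, small_nets):
        state = factorize(small_nets, n_components=3, max_iter=20, random_state=9)
        m = ATVNetNMF(n_components=3, max_iter=20, random_state=9).fit(small_nets)
        np.testing.assert_array_equal(state.G1, m.G1_)
        assert state.iterations_run == m.n_iter_


class TestKKTResidual:
    def test_zero_at_exact_factorization(self):
        R11, R12, R22, G1, G2, S11, S22 = exact_instance()
        res = kkt_residual(R11, R12, R22, G1, G2, S11, S22, alpha=1.0, beta=1.0)
        assert res < 1e-8

    def test_gradients_match_central_differences(self):
        # graph-regularized objective is smooth in the factors; the TV term
        # is checked separately with its exponent map frozen
        rng = np.random.default_rng(3)
        n1, n2, k = 6, 4, 2
        nets = random_network_triple(n1, n2, n_samples=10, seed=3)
        L1 = build_graph_laplacian(nets.R11, 2)
        L2 = build_graph_laplacian(nets.R22, 2)
        G1, G2, S11, S22 = initialize_factors(n1, n2, k, random_state=3)
        kw = dict(alpha=1.5, beta=2.25, lambda1=0.06, lambda2=0.09, L1=L1, L2=L2)
        grads = objective_gradients(nets.R11, nets.R12, nets.R22,
                                    G1, G2, S11, S22, **kw)

        def f(G1=G1, G2=G2, S11=S11, S22=S22):
            return objective(nets.R11, nets.R12, nets.R22, G1, G2, S11, S22, **kw)

        h = 1e-6
        factors = {"G1": G1, "G2": G2, "S11": S11, "S22": S22}
        for name, F in factors.items():
            fd = np.zeros_like(F)
            for idx in np.ndindex(F.shape):
                Fp, Fm = F.copy(), F.copy()
                Fp[idx] += h
                Fm[idx] -= h
                fd[idx] = (f(**{name: Fp}) - f(**{name: Fm})) / (2 * h)
            if name in ("S11", "S22"):
                # the analytic form assumes symmetric S; symmetrize the FD
                fd = (fd + fd.T) / 2
            np.testing.assert_allclose(grads[name], fd, atol=1e-4, rtol=1e-4)

    def test_tv_gradient_matches_frozen_p_finite_differences(self):
        rng = np.random.default_rng(8)
        G = rng.uniform(0.2, 1.0, size=(6, 4))
        eps = 1e-6
        from atvnetnmf.tv import tv_field

        p0 = tv_field(G, eps).p_map  # exponent frozen at the base point

        def frozen_energy(M):
            gx, gy = forward_gradient(M)
            m = np.sqrt(gx ** 2 + gy ** 2 + eps ** 2)
            return np.sum(m ** p0 / p0)

        analytic = -tv_divergence(G, p_map=p0, grad_epsilon=eps)
        h = 1e-7
        fd = np.zeros_like(G)
        for idx in np.ndindex(G.shape):
            Gp, Gm = G.copy(), G.copy()
            Gp[idx] += h
            Gm[idx] -= h
            fd[idx] = (frozen_energy(Gp) - frozen_energy(Gm)) / (2 * h)
        np.testing.assert_allclose(analytic, fd, atol=1e-4)

    def test_residual_decreases_with_iterations(self):
        nets = random_network_triple(15, 12, n_samples=14, seed=4)
        res = {}
        for iters in (10, 500):
            m = ATVNetNMF(n_components=3, max_iter=iters, graph=False, tv=False,
                          random_state=4).fit(nets)
            res[iters] = m.kkt_residual(nets)
        assert res[500] < res[10]


class TestReconstructionCorrelation:
    def test_identity_and_affine_invariance(self, rng):
        R = rng.uniform(0, 1, size=(8, 8))
        assert reconstruction_correlation(R, R) == pytest.approx(1.0)
        assert reconstruction_correlation(R, 2.5 * R + 0.3) == pytest.approx(1.0)

    def test_matches_two_pass_oracle(self, rng):
        R = rng.uniform(0, 1, size=(7, 5))
        Rh = rng.uniform(0, 1, size=(7, 5))
        a, b = R.ravel(), Rh.ravel()
        am, bm = a.mean(), b.mean()
        expected = (np.sum((a - am) * (b - bm))
                    / np.sqrt(np.sum((a - am) ** 2) * np.sum((b - bm) ** 2)))
        assert reconstruction_correlation(R, Rh) == pytest.approx(expected,
                                                                  rel=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            reconstruction_correlation(np.ones((3, 3)), np.eye(3))
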