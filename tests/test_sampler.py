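"""Full-conditional updates against conjugate closed forms, and chain
contracts (determinism, reductions, stored-draw invariants)."""

import numpy as np
import pytest

from sgbfa.data import ChainConfig, Hyperparams, ModalityData
from sgbfa.graph import FeatureGraph, check_compatibility
from sgbfa.sampler import (
    AugmentationState,
    MCMCState,
    ModelContext,
    augment,
    mh_update_A_mod,
    posterior_mean_mu,
    run_chain,
    update_m_rho,
    update_regression,
    update_shrinkage,
    update_W,
    update_Z,
)
from sgbfa.simulate import ScenarioSpec, simulate_dataset


def _gauss_mod(X, rho):
    return ModalityData(name="g", X=np.asarray(X, float), family="gaussian",
                        precision=np.asarray(rho, float))


def _ctx(mods, Y=None, L=1, hyper=None):
    return ModelContext(mods, Y, FeatureGraph.empty(mods),
                        hyper or Hyperparams(), L)


def _state(ctx, **kw):
    p, L, n = ctx.p, ctx.L, ctx.n
    defaults = dict(
        W=np.zeros((p, L)), Z=np.zeros((L, n)), m=np.zeros(p),
        rho=np.where(ctx.gaussian_mask, 1.0, np.nan),
        B=np.zeros((ctx.p_y, L)), beta0=np.zeros(ctx.p_y),
        rho_y=np.ones(ctx.p_y), Phi=np.ones((ctx.H, L)),
        A_mod=np.zeros((p, L)), Lambda_y=np.ones((ctx.p_y, L)),
        Omega=np.eye(p),
    )
    defaults.update(kw)
    st = MCMCState(**defaults)
    st.aug = AugmentationState(
        s_W=np.ones((p, L)), s_B=np.ones((ctx.p_y, L)),
        pg=[None] * ctx.H,
    )
    return st


class _ZeroNoise:
    """Stub generator returning zero noise: draws collapse to the
    conditional mean, exposing the deterministic part of each update."""

    def standard_normal(self, shape=None):
        return np.zeros(shape if shape is not None else ())


class TestAugment:
    def test_zero_loading_no_overflow(self, rng):
        mods = [_gauss_mod(np.zeros((2, 3)), [1.0, 1.0])]
        ctx = _ctx(mods, L=2)
        st = _state(ctx)  # W identically zero
        aug = augment(st, ctx, rng)
        assert np.all(np.isfinite(aug.s_W)) and np.all(aug.s_W > 0)

    def test_pg_variables_for_logit_blocks(self, rng):
        mods = [ModalityData(name="b", X=np.ones((2, 3)), family="binomial",
                             trials=np.array([2, 3]))]
        ctx = _ctx(mods, L=1)
        st = _state(ctx, rho=np.full(2, np.nan))
        aug = augment(st, ctx, rng)
        assert aug.pg[0].shape == (2, 3) and np.all(aug.pg[0] > 0)


class TestUpdateW:
    def test_single_coefficient_ridge_closed_form(self):
        rng = np.random.default_rng(1)
        n, rho, s = 12, 2.0, 0.5
        z = rng.normal(size=(1, n))
        x = 1.3 * z + rng.normal(size=(1, n)) / np.sqrt(rho)
        mods = [_gauss_mod(x, [rho])]
        ctx = _ctx(mods, L=1)
        prec = rho * np.sum(z ** 2) + 1.0 / s
        mean = rho * np.sum(z * x) / prec
        draws = np.empty(4000)
        for i in range(draws.size):
            st = _state(ctx, Z=z.copy(), rho=np.array([rho]))
            st.aug.s_W[:] = s
            update_W(st, ctx, np.random.default_rng(i))
            draws[i] = st.W[0, 0]
        assert draws.mean() == pytest.approx(mean, abs=4 / np.sqrt(prec *
                                                                   draws.size))
        assert draws.var() == pytest.approx(1 / prec, rel=0.1)

    def test_infinite_shrinkage_collapses_to_zero(self):
        rng = np.random.default_rng(2)
        mods = [_gauss_mod(rng.normal(size=(1, 6)), [1.0])]
        ctx = _ctx(mods, L=1)
        st = _state(ctx, Z=rng.normal(size=(1, 6)))
        st.aug.s_W[:] = 1e-14
        update_W(st, ctx, rng)
        assert abs(st.W[0, 0]) < 1e-5


class TestUpdateZ:
    def test_standard_normal_when_unloaded(self):
        rng = np.random.default_rng(3)
        mods = [_gauss_mod(rng.normal(size=(2, 600)), [1.0, 1.0])]
        ctx = _ctx(mods, L=1)
        st = _state(ctx)  # W = 0, no outcomes
        update_Z(st, ctx, rng)
        assert st.Z.mean() == pytest.approx(0.0, abs=4 / np.sqrt(600))
        assert st.Z.var() == pytest.approx(1.0, rel=0.15)

    def test_one_factor_posterior_closed_form(self):
        rng = np.random.default_rng(4)
        p, rho = 6, 1.5
        w = rng.normal(size=(p, 1))
        x = rng.normal(size=(p, 1))
        mods = [_gauss_mod(x, np.full(p, rho))]
        ctx = _ctx(mods, L=1)
        prec = 1.0 + rho * np.sum(w ** 2)
        mean = rho * float((w.T @ x).item()) / prec
        draws = np.empty(4000)
        for i in range(draws.size):
            st = _state(ctx, W=w.copy(), rho=np.full(p, rho))
            update_Z(st, ctx, np.random.default_rng(100 + i))
            draws[i] = st.Z[0, 0]
        assert draws.mean() == pytest.approx(mean,
                                             abs=4 / np.sqrt(prec * 4000))
        assert draws.var() == pytest.approx(1 / prec, rel=0.1)


class TestRegressionAndLocation:
    def test_intercept_is_shrunk_mean_with_null_factors(self):
        rng = np.random.default_rng(5)
        n = 40
        y = rng.normal(loc=2.0, size=(1, n))
        mods = [_gauss_mod(rng.normal(size=(1, n)), [1.0])]
        hyper = Hyperparams(sigma_b2=4.0)
        ctx = _ctx(mods, Y=y, L=1, hyper=hyper)
        rho_y = 1.7
        prec = rho_y * n + 1.0 / hyper.sigma_b2
        shrunk = rho_y * y.sum() / (rho_y * n + 1.0 / hyper.sigma_b2)
        draws = np.empty(3000)
        for i in range(draws.size):
            st = _state(ctx, rho_y=np.array([rho_y]))
            update_regression(st, ctx, np.random.default_rng(200 + i))
            draws[i] = st.beta0[0]
        assert draws.mean() == pytest.approx(shrunk,
                                             abs=4 / np.sqrt(prec * 3000))

    def test_bayesian_ridge_closed_form_L1(self):
        rng = np.random.default_rng(6)
        n, rho_y, s = 30, 2.0, 0.7
        z = rng.normal(size=(1, n))
        y = 1.4 * z + rng.normal(size=(1, n))
        hyper = Hyperparams(sigma_b2=100.0)
        mods = [_gauss_mod(rng.normal(size=(1, n)), [1.0])]
        ctx = _ctx(mods, Y=y, L=1, hyper=hyper)
        G = np.vstack([np.ones((1, n)), z])
        P = rho_y * G @ G.T + np.diag([1 / hyper.sigma_b2, 1 / s])
        mean = np.linalg.solve(P, rho_y * G @ y[0])
        draws = np.empty((3000, 2))
        for i in range(draws.shape[0]):
            st = _state(ctx, Z=z.copy(), rho_y=np.array([rho_y]))
            st.aug.s_B[:] = s
            update_regression(st, ctx, np.random.default_rng(300 + i))
            draws[i] = st.beta0[0], st.B[0, 0]
        assert np.allclose(draws.mean(0), mean, atol=0.05)

    def test_location_is_shrunk_row_mean_without_loadings(self):
        rng = np.random.default_rng(7)
        n, rho = 50, 2.0
        x = rng.normal(loc=1.0, size=(1, n))
        hyper = Hyperparams(sigma_m2=10.0)
        mods = [_gauss_mod(x, [rho])]
        ctx = _ctx(mods, L=1, hyper=hyper)
        prec = rho * n + 1.0 / hyper.sigma_m2
        shrunk = rho * x.sum() / prec
        draws = np.empty(3000)
        for i in range(draws.size):
            st = _state(ctx)
            update_m_rho(st, ctx, np.random.default_rng(400 + i))
            draws[i] = st.m[0]
        assert draws.mean() == pytest.approx(shrunk,
                                             abs=4 / np.sqrt(prec * 3000))

    def test_location_update_runs_for_logit_blocks(self, rng):
        mods = [ModalityData(name="b", X=np.ones((2, 4)), family="binomial",
                             trials=np.array([1, 2]))]
        ctx = _ctx(mods, L=1)
        st = _state(ctx, rho=np.full(2, np.nan))
        st.aug = augment(st, ctx, rng)
        update_m_rho(st, ctx, rng)
        assert np.all(np.isfinite(st.m))
        assert np.all(np.isnan(st.rho))  # no Gaussian precision exists


class TestShrinkage:
    def test_phi_posterior_moments_at_zero_loadings(self):
        mods = [_gauss_mod(np.zeros((7, 3)), np.ones(7))]
        hyper = Hyperparams(a_phi=2.0, b_phi=3.0)
        ctx = _ctx(mods, L=2, hyper=hyper)
        draws = np.empty((4000, 2))
        for i in range(draws.shape[0]):
            st = _state(ctx)
            update_shrinkage(st, ctx, np.random.default_rng(500 + i))
            draws[i] = st.Phi[0]
        shape, rate = hyper.a_phi + 7, hyper.b_phi
        assert np.allclose(draws.mean(0), shape / rate, rtol=0.05)
        assert np.allclose(draws.var(0), shape / rate ** 2, rtol=0.12)

    def test_phi_mean_decreases_with_weighted_loadings(self):
        mods = [_gauss_mod(np.zeros((4, 3)), np.ones(4))]
        hyper = Hyperparams(a_phi=1.0, b_phi=1.0)
        ctx = _ctx(mods, L=1, hyper=hyper)
        means = []
        for scale in [0.0, 0.5, 2.0, 5.0]:
            acc = 0.0
            for i in range(1500):
                st = _state(ctx, W=np.full((4, 1), scale))
                update_shrinkage(st, ctx, np.random.default_rng(600 + i))
                acc += st.Phi[0, 0]
            means.append(acc / 1500)
        assert means == sorted(means, reverse=True)

    def test_lambda_y_matches_griddy_posterior(self):
        """Gamma prior x Laplace term for a single coefficient vs a
        numerically normalized grid posterior."""
        beta = 0.8
        a_l, b_l = 2.0, 1.5
        hyper = Hyperparams(a_lambda=a_l, b_lambda=b_l)
        mods = [_gauss_mod(np.zeros((1, 3)), np.ones(1))]
        ctx = _ctx(mods, Y=np.zeros((1, 3)), L=1, hyper=hyper)
        grid = np.linspace(1e-6, 40, 40000)
        # posterior ∝ lambda^{a} e^{-(b + |beta|) lambda}  (prior x lik term)
        logd = a_l * np.log(grid) - (b_l + abs(beta)) * grid
        dens = np.exp(logd - logd.max())
        dens /= dens.sum()
        grid_mean = float(np.sum(dens * grid))
        acc = 0.0
        reps = 4000
        for i in range(reps):
            st = _state(ctx, B=np.array([[beta]]))
            update_shrinkage(st, ctx, np.random.default_rng(700 + i))
            acc += st.Lambda_y[0, 0]
        assert acc / reps == pytest.approx(grid_mean, rel=0.03)


class TestMHAmod:
    def test_zero_step_always_accepts_and_preserves_state(self, rng):
        mods = [_gauss_mod(np.zeros((3, 4)), np.ones(3))]
        ctx = _ctx(mods, L=2)
        st = _state(ctx, A_mod=rng.normal(size=(3, 2)))
        before = st.A_mod.copy()
        acc = mh_update_A_mod(st, ctx, np.zeros((3, 2)), rng)
        assert acc.all()
        assert np.array_equal(st.A_mod, before)


@pytest.fixture(scope="module")
def small_sim():
    spec = ScenarioSpec(structure="ai", data_type="gaussian",
                        p_per_modality=10, n=40, n_pathways=1,
                        n_outcomes=1, graph_variant="G2", seed=3)
    return simulate_dataset(spec)


class TestChainContracts:
    def test_same_seed_bitwise_identical(self, small_sim):
        cfg = ChainConfig(n_iter=40, n_burnin=20, thin=2, seed=9)
        h = Hyperparams()
        out = []
        for _ in range(2):
            s = run_chain(small_sim.modalities, small_sim.Y, small_sim.graph,
                          h, cfg, L=4)
            out.append(s)
        for key in ("W", "Z", "m", "B", "beta0", "Phi", "A_mod",
                    "log_posterior"):
            assert np.array_equal(getattr(out[0], key), getattr(out[1], key))

    def test_unsupervised_equals_zero_outcome_supervised(self, small_sim):
        cfg = ChainConfig(n_iter=30, n_burnin=10, thin=2, seed=4)
        h = Hyperparams()
        a = run_chain(small_sim.modalities, None, small_sim.graph, h, cfg,
                      L=4)
        b = run_chain(small_sim.modalities, np.zeros((0, small_sim.spec.n)),
                      small_sim.graph, h, cfg, L=4)
        assert np.array_equal(a.W, b.W)
        assert np.array_equal(a.Z, b.Z)

    def test_stored_draw_invariants(self, small_sim):
        cfg = ChainConfig(n_iter=40, n_burnin=20, thin=2, seed=5)
        s = run_chain(small_sim.modalities, small_sim.Y, small_sim.graph,
                      Hyperparams(), cfg, L=4)
        assert s.n_draws == cfg.n_stored == len(s.Omega)
        assert np.all(np.isfinite(s.log_posterior))
        assert np.all(s.Phi > 0) and np.all(s.Lambda_y > 0)
        for Om in s.Omega:
            assert check_compatibility(Om.toarray(), small_sim.graph)

    def test_gaussian_recovery_beats_trivial_baseline(self):
        from sgbfa.evaluate import rre

        spec = ScenarioSpec(structure="ai", data_type="gaussian",
                            p_per_modality=10, n=100, n_pathways=1,
                            graph_variant="G2", seed=6)
        sim = simulate_dataset(spec)
        cfg = ChainConfig(n_iter=300, n_burnin=150, thin=3, seed=7)
        s = run_chain(sim.modalities, None, sim.graph, Hyperparams(), cfg,
                      L=4)
        mu_hat, _ = posterior_mean_mu(s)
        assert rre(np.zeros_like(sim.mu), sim.mu) == pytest.approx(1.0)
        assert rre(mu_hat, sim.mu) < 0.5

    def test_conditional_moments_equivariant_under_permutation(self):
        """Permuting features (null graph, Omega = I) permutes the W and m
        full-conditional means exactly (zero-noise draws)."""
        rng = np.random.default_rng(8)
        p, n, L = 5, 7, 2
        X = rng.normal(size=(p, n))
        Z = rng.normal(size=(L, n))
        sW = np.abs(rng.normal(size=(p, L))) + 0.5
        perm = np.array([3, 0, 4, 1, 2])

        def w_means(Xv, sv):
            mods = [_gauss_mod(Xv, np.ones(p))]
            ctx = _ctx(mods, L=L)
            st = _state(ctx, Z=Z.copy())
            st.aug.s_W = sv.copy()
            update_W(st, ctx, _ZeroNoise())
            return st.W

        base = w_means(X, sW)
        permuted = w_means(X[perm], sW[perm])
        assert np.allclose(permuted, base[perm], atol=1e-12)


class TestPosteriorMeanMu:
    def _samples(self, W, Z, m, B=None, beta0=None):
        import scipy.sparse as sp
        from sgbfa.sampler import PosteriorSamples

        T = W.shape[0]
        p_y = 0 if B is None else B.shape[1]
        return PosteriorSamples(
            W=W, Z=Z, m=m,
            rho=np.ones((T, W.shape[1])),
            B=np.zeros((T, p_y, W.shape[2])) if B is None else B,
            beta0=np.zeros((T, p_y)) if beta0 is None else beta0,
            rho_y=np.ones((T, p_y)),
            Phi=np.ones((T, 1, W.shape[2])),
            Lambda_y=np.ones((T, p_y, W.shape[2])),
            A_mod=np.zeros((T, W.shape[1], W.shape[2])),
            Omega=[], log_posterior=np.zeros(T), log_likelihood=np.zeros(T),
            mh_acceptance_rate=0.3,
            config=ChainConfig(n_iter=2, n_burnin=0, thin=1),
            modality_names=["m0"], block_sizes=[W.shape[1]],
        )

    def test_single_draw_identity(self, rng):
        W = rng.normal(size=(1, 3, 2))
        Z = rng.normal(size=(1, 2, 4))
        m = rng.normal(size=(1, 3))
        mu, _ = posterior_mean_mu(self._samples(W, Z, m))
        assert np.allclose(mu, m[0][:, None] + W[0] @ Z[0])

    def test_constant_shift_linearity(self, rng):
        W = rng.normal(size=(3, 2, 2))
        Z = rng.normal(size=(3, 2, 4))
        m = rng.normal(size=(3, 2))
        mu, _ = posterior_mean_mu(self._samples(W, Z, m))
        mu2, _ = posterior_mean_mu(self._samples(W, Z, m + 1.0))
        assert np.allclose(mu2, mu + 1.0, atol=1e-12)

    def test_three_draw_brute_force(self, rng):
        W = rng.normal(size=(3, 2, 1))
        Z = rng.normal(size=(3, 1, 2))
        m = rng.normal(size=(3, 2))
        mu, _ = posterior_mean_mu(self._samples(W, Z, m))
        oracle = np.mean(
            [m[t][:, None] + W[t] @ Z[t] for t in range(3)], axis=0)
        assert np.allclose(mu, oracle, atol=1e-12)
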