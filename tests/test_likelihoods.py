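"""Likelihood terms against closed forms and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from sgbfa.data import (
    FactorState,
    Hyperparams,
    ModalityData,
    OutcomeState,
    ShrinkageState,
    ValidationError,
)
from sgbfa.graph import FeatureGraph
from sgbfa.likelihoods import (
    joint_log_posterior,
    linearize,
    loglik_modality,
    loglik_outcomes,
)
from sgbfa import priors


class TestLinearize:
    def test_zero_loadings_give_location_columns(self):
        fs = FactorState(W=np.zeros((3, 2)), Z=np.ones((2, 4)),
                         m=np.ones(3))
        mu = linearize(fs)
        assert np.array_equal(mu, np.ones((3, 4)))

    def test_rank_one_outer_product(self):
        w = np.array([[1.0], [2.0], [-0.5]])
        z = np.array([[3.0, -1.0, 0.0]])
        fs = FactorState(W=w, Z=z, m=np.zeros(3))
        assert np.allclose(linearize(fs), w @ z)

    def test_matches_triple_loop_oracle(self, rng):
        W = rng.normal(size=(3, 2))
        Z = rng.normal(size=(2, 4))
        m = rng.normal(size=3)
        mu = linearize(FactorState(W=W, Z=Z, m=m))
        oracle = np.empty((3, 4))
        for j in range(3):
            for i in range(4):
                acc = m[j]
                for l in range(2):
                    acc += W[j, l] * Z[l, i]
                oracle[j, i] = acc
        assert np.allclose(mu, oracle, atol=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValidationError):
            FactorState(W=np.zeros((3, 2)), Z=np.zeros((3, 4)), m=np.zeros(3))


class TestModalityLoglik:
    def test_gaussian_residual_free_cell(self):
        mod = ModalityData(name="g", X=np.array([[0.7]]), family="gaussian",
                           precision=np.array([1.0]))
        val = loglik_modality(mod, np.array([[0.7]]))
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    @pytest.mark.parametrize("n,x,expected", [
        (1, 1, np.log(0.5)),
        (2, 2, np.log(0.25)),
    ])
    def test_binomial_at_even_odds(self, n, x, expected):
        mod = ModalityData(name="b", X=np.array([[float(x)]]),
                           family="binomial", trials=np.array([n]))
        assert loglik_modality(mod, np.zeros((1, 1))) == \
            pytest.approx(expected, abs=1e-12)

    def test_negative_binomial_geometric_at_half(self):
        mod = ModalityData(name="nb", X=np.array([[0.0]]),
                           family="negative_binomial",
                           failures=np.array([1.0]))
        assert loglik_modality(mod, np.zeros((1, 1))) == \
            pytest.approx(np.log(0.5), abs=1e-12)

    def test_gaussian_matches_scipy_cellwise(self, tiny_gaussian):
        for mod in tiny_gaussian:
            mu = np.linspace(-1, 1, mod.p * mod.n).reshape(mod.p, mod.n)
            oracle = sum(
                stats.norm.logpdf(mod.X[j, i], mu[j, i],
                                  1.0 / np.sqrt(mod.precision[j]))
                for j in range(mod.p) for i in range(mod.n)
            )
            assert loglik_modality(mod, mu) == pytest.approx(oracle,
                                                             abs=1e-10)

    def test_binomial_matches_scipy(self, tiny_mixed):
        mod = tiny_mixed[1]
        mu = np.linspace(-0.5, 1.2, mod.p * mod.n).reshape(mod.p, mod.n)
        prob = 1 / (1 + np.exp(-mu))
        oracle = np.sum(stats.binom.logpmf(mod.X, mod.trials[:, None], prob))
        assert loglik_modality(mod, mu) == pytest.approx(oracle, abs=1e-10)

    def test_negative_binomial_matches_scipy(self, tiny_mixed):
        mod = tiny_mixed[2]
        mu = np.array([[0.3, -0.4, 0.0, 1.1]])
        prob = 1 / (1 + np.exp(-mu))
        # scipy nbinom: successes-before-r-failures parametrization
        oracle = np.sum(stats.nbinom.logpmf(mod.X, mod.failures[:, None],
                                            1 - prob))
        assert loglik_modality(mod, mu) == pytest.approx(oracle, abs=1e-10)

    def test_binomial_trials_one_is_bernoulli(self, rng):
        X = (rng.random((3, 6)) < 0.5).astype(float)
        mod = ModalityData(name="b", X=X, family="binomial",
                           trials=np.ones(3, dtype=int))
        mu = rng.normal(size=(3, 6))
        prob = 1 / (1 + np.exp(-mu))
        bern = np.sum(X * np.log(prob) + (1 - X) * np.log(1 - prob))
        assert loglik_modality(mod, mu) == pytest.approx(bern, abs=1e-10)

    def test_nb_approaches_poisson_at_large_r(self):
        r = 1e4
        mean = 3.0
        xs = np.arange(0, 9, dtype=float)[None, :]
        mod = ModalityData(name="nb", X=xs, family="negative_binomial",
                           failures=np.array([r]))
        mu = np.full_like(xs, np.log(mean / r))
        nb_cells = np.array([
            loglik_modality(
                ModalityData(name="nb", X=np.array([[x]]),
                             family="negative_binomial",
                             failures=np.array([r])),
                np.array([[np.log(mean / r)]]))
            for x in xs[0]
        ])
        pois = stats.poisson.logpmf(xs[0], mean)
        assert np.max(np.abs(nb_cells - pois)) < 1e-3

    def test_domain_violation_raises(self):
        with pytest.raises(ValidationError):
            ModalityData(name="b", X=np.array([[3.0]]), family="binomial",
                         trials=np.array([2]))
        with pytest.raises(ValidationError):
            ModalityData(name="nb", X=np.array([[-1.0]]),
                         family="negative_binomial", failures=np.array([1.0]))


class TestOutcomeLoglik:
    def test_exact_fit_constant(self):
        Z = np.array([[0.5, -0.5]])
        B = np.array([[2.0]])
        beta0 = np.array([0.3])
        Y = beta0[:, None] + B @ Z
        st = OutcomeState(Y=Y, B=B, beta0=beta0, rho_y=np.array([1.0]))
        assert loglik_outcomes(st, Z) == pytest.approx(-np.log(2 * np.pi),
                                                       abs=1e-12)

    def test_quadratic_in_residual(self):
        Z = np.zeros((1, 3))
        base = OutcomeState(Y=np.zeros((1, 3)), B=np.zeros((1, 1)),
                            beta0=np.zeros(1), rho_y=np.array([2.0]))
        shifted = OutcomeState(Y=np.full((1, 3), 0.4), B=np.zeros((1, 1)),
                               beta0=np.zeros(1), rho_y=np.array([2.0]))
        delta = loglik_outcomes(shifted, Z) - loglik_outcomes(base, Z)
        assert delta == pytest.approx(-2.0 * (0.4 ** 2 * 3) / 2, abs=1e-12)

    def test_matches_cellwise_normal_oracle(self, rng):
        Z = rng.normal(size=(2, 5))
        st = OutcomeState(Y=rng.normal(size=(3, 5)),
                          B=rng.normal(size=(3, 2)),
                          beta0=rng.normal(size=3),
                          rho_y=np.array([1.0, 0.5, 2.0]))
        mu_y = st.beta0[:, None] + st.B @ Z
        oracle = sum(
            stats.norm.logpdf(st.Y[j, i], mu_y[j, i],
                              1 / np.sqrt(st.rho_y[j]))
            for j in range(3) for i in range(5)
        )
        assert loglik_outcomes(st, Z) == pytest.approx(oracle, abs=1e-10)


def _random_instance(seed=3):
    rng = np.random.default_rng(seed)
    mods = [
        ModalityData(name="a", X=rng.normal(size=(2, 4)), family="gaussian",
                     precision=np.array([1.0, 2.0])),
        ModalityData(name="b",
                     X=rng.binomial(1, 0.5, size=(2, 4)).astype(float),
                     family="binomial", trials=np.ones(2, dtype=int)),
    ]
    graph = FeatureGraph(
        modality_names=["a", "b"],
        feature_ids={m.name: list(m.feature_ids) for m in mods},
        edges={"a": {(0, 1)}, "b": set()},
    )
    fs = FactorState(W=rng.normal(size=(4, 2)), Z=rng.normal(size=(2, 4)),
                     m=rng.normal(size=4))
    shrink = ShrinkageState(Phi=np.abs(rng.normal(size=(2, 2))) + 0.5,
                            A_mod=rng.normal(size=(4, 2)) * 0.3,
                            Lambda_y=np.abs(rng.normal(size=(1, 2))) + 0.5)
    Omega = np.eye(4)
    Omega[0, 1] = Omega[1, 0] = 0.3
    out = OutcomeState(Y=rng.normal(size=(1, 4)),
                       B=rng.normal(size=(1, 2)), beta0=rng.normal(size=1),
                       rho_y=np.array([1.2]))
    return mods, graph, fs, shrink, Omega, out


class TestJointLogPosterior:
    def test_perturbing_one_loading_changes_only_its_terms(self):
        mods, graph, fs, shrink, Omega, out = _random_instance()
        hyper = Hyperparams()
        base = joint_log_posterior(mods, fs, shrink, Omega, graph, hyper, out)
        W2 = fs.W.copy()
        W2[1, 0] += 0.37
        fs2 = FactorState(W=W2, Z=fs.Z, m=fs.m)
        new = joint_log_posterior(mods, fs2, shrink, Omega, graph, hyper, out)
        # expected: delta likelihood of modality a + delta Laplace prior term
        from sgbfa.likelihoods import linearize, loglik_modality

        d_lik = loglik_modality(mods[0], linearize(fs2)[:2]) - \
            loglik_modality(mods[0], linearize(fs)[:2])
        rate = shrink.Phi[0, 0] * np.exp(shrink.A_mod[1, 0])
        d_prior = -rate * (abs(W2[1, 0]) - abs(fs.W[1, 0]))
        assert new - base == pytest.approx(d_lik + d_prior, abs=1e-9)

    def test_equals_sum_of_exposed_terms(self):
        mods, graph, fs, shrink, Omega, out = _random_instance()
        hyper = Hyperparams()
        from sgbfa.data import block_slices
        from sgbfa.likelihoods import (linearize, loglik_modality,
                                       loglik_outcomes)

        mu = linearize(fs)
        total = 0.0
        for sl, mod in zip(block_slices(mods), mods):
            total += loglik_modality(mod, mu[sl])
        total += loglik_outcomes(out, fs.Z)
        total += priors.logprior_laplace_W(fs.W, shrink.Lambda_mod,
                                           shrink.Phi, block_slices(mods))
        total += priors.logprior_phi(shrink.Phi, hyper.a_phi, hyper.b_phi)
        total += priors.logprior_A_mod(shrink.A_mod, Omega, hyper.nu1,
                                       hyper.nu2)
        total += priors.logprior_omega(Omega, graph, hyper.eta, hyper.epsilon)
        total += priors.logprior_laplace_B(out.B, shrink.Lambda_y)
        total += priors.logprior_lambda_y(shrink.Lambda_y, hyper.a_lambda,
                                          hyper.b_lambda)
        total += priors.logprior_nuisance(fs.m, fs.Z, out.beta0, out.rho_y,
                                          hyper, zeta_y=out.zeta_y)
        total += priors.logprior_gamma_precisions(
            mods[0].precision, np.full(2, hyper.zeta))
        val = joint_log_posterior(mods, fs, shrink, Omega, graph, hyper, out)
        assert val == pytest.approx(total, abs=1e-9)

    def test_off_graph_entry_gives_minus_inf(self):
        mods, graph, fs, shrink, Omega, out = _random_instance()
        bad = Omega.copy()
        bad[2, 3] = bad[3, 2] = 0.2  # no edge in modality "b"
        val = joint_log_posterior(mods, fs, shrink, bad, graph,
                                  Hyperparams(), out)
        assert val == -np.inf

    def test_invariant_to_modality_order(self):
        mods, graph, fs, shrink, Omega, out = _random_instance()
        hyper = Hyperparams()
        base = joint_log_posterior(mods, fs, shrink, Omega, graph, hyper, out)
        # reverse modality order, permuting every stacked object coherently
        perm = np.array([2, 3, 0, 1])
        mods_r = [mods[1], mods[0]]
        graph_r = FeatureGraph(
            modality_names=["b", "a"],
            feature_ids={m.name: list(m.feature_ids) for m in mods_r},
            edges={"a": {(0, 1)}, "b": set()},
        )
        fs_r = FactorState(W=fs.W[perm], Z=fs.Z, m=fs.m[perm])
        shrink_r = ShrinkageState(Phi=shrink.Phi[::-1].copy(),
                                  A_mod=shrink.A_mod[perm],
                                  Lambda_y=shrink.Lambda_y)
        Omega_r = Omega[np.ix_(perm, perm)]
        val = joint_log_posterior(mods_r, fs_r, shrink_r, Omega_r, graph_r,
                                  hyper, out)
        assert val == pytest.approx(base, abs=1e-9)
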