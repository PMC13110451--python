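"""Gibbs/Metropolis MCMC engine for the supervised graph-guided factor model.

Augmentation makes every full conditional tractable:

* Laplace priors on loadings W and coefficients B are written as
  normal-exponential scale mixtures, giving Gaussian row conditionals.
* Binomial / negative-binomial cells get Pólya-Gamma variables, turning the
  logit likelihood into a Gaussian pseudo-likelihood with per-cell working
  precision omega and working linear term kappa.
* The modality- and outcome-level shrinkage rates (Phi, Lambda_y) are
  updated from their collapsed conditionals given (W, B) with the mixture
  scales integrated out (a partially collapsed Gibbs step: the scales are
  redrawn from their exact conditional at the top of every sweep before
  they are conditioned on again).
* The log feature-shrinkage matrix A_mod is updated by an adaptive
  per-entry Gaussian random walk, scanning graph-coloring classes so that
  conditionally independent entries are accepted in parallel.
* Omega is refreshed from its G-Wishart full conditional.

Sweep order: augment -> W -> Z -> (m, rho) -> regression -> (Phi, Lambda_y)
-> A_mod (MH) -> Omega.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .data import (
    ChainConfig,
    FactorState,
    Hyperparams,
    ModalityData,
    OutcomeState,
    ShrinkageState,
    ValidationError,
    block_slices,
    check_shared_n,
)
from .graph import FeatureGraph, GraphPrecisionSampler
from .likelihoods import joint_log_posterior, loglik_full
from .polya_gamma import random_polyagamma

__all__ = [
    "AugmentationState",
    "MCMCState",
    "ModelContext",
    "PosteriorSamples",
    "augment",
    "update_W",
    "update_Z",
    "update_regression",
    "update_m_rho",
    "update_shrinkage",
    "mh_update_A_mod",
    "run_chain",
    "posterior_mean_mu",
    "sample_prior_state",
    "resample_observations",
]

_MIN_ABS = 1e-10  # |w| floor inside inverse-Gaussian means


@dataclass
class AugmentationState:
    """Auxiliary variables of one sweep.

    ``s_W``/``s_B`` are the Laplace normal-exponential mixing variances;
    ``pg`` holds one Pólya-Gamma matrix per non-Gaussian modality (None for
    Gaussian blocks).
    """

    s_W: np.ndarray
    s_B: np.ndarray
    pg: List[Optional[np.ndarray]]


@dataclass
class MCMCState:
    """All current parameter values of the chain."""

    W: np.ndarray          # (p, L)
    Z: np.ndarray          # (L, n)
    m: np.ndarray          # (p,)
    rho: np.ndarray        # (p,) Gaussian precisions; NaN on non-Gaussian rows
    B: np.ndarray          # (p_y, L)
    beta0: np.ndarray      # (p_y,)
    rho_y: np.ndarray      # (p_y,)
    Phi: np.ndarray        # (H, L)
    A_mod: np.ndarray      # (p, L)
    Lambda_y: np.ndarray   # (p_y, L)
    Omega: np.ndarray      # (p, p) block-diagonal, graph-compatible
    aug: Optional[AugmentationState] = None

    def factor_state(self) -> FactorState:
        return FactorState(W=self.W, Z=self.Z, m=self.m)


class ModelContext:
    """Immutable problem description shared by all update steps."""

    def __init__(
        self,
        modalities: Sequence[ModalityData],
        Y: Optional[np.ndarray],
        graph: FeatureGraph,
        hyper: Hyperparams,
        L: int,
    ):
        self.modalities = list(modalities)
        self.n = check_shared_n(self.modalities)
        self.slices = block_slices(self.modalities)
        self.p = sum(m.p for m in self.modalities)
        self.H = len(self.modalities)
        self.L = L
        self.graph = graph
        self.hyper = hyper
        if Y is not None:
            Y = np.asarray(Y, dtype=float)
            if Y.ndim != 2 or Y.shape[1] != self.n:
                raise ValidationError("Y must be (p_y, n)")
        self.Y = Y
        self.p_y = 0 if Y is None else Y.shape[0]
        if graph is not None:
            if not graph.matches_modalities(self.modalities):
                raise ValidationError(
                    "graph feature ids/order do not match the modalities"
                )
            self.color_classes = self._color_classes(graph)
            self.omega_sampler = GraphPrecisionSampler(
                graph, hyper.eta, hyper.epsilon
            )
        else:
            self.color_classes = [np.arange(self.p)]
            self.omega_sampler = None
        self.gaussian_mask = np.concatenate([
            np.full(m.p, m.family == "gaussian") for m in self.modalities
        ])

    def _color_classes(self, graph: FeatureGraph) -> List[np.ndarray]:
        colors = np.zeros(self.p, dtype=int)
        for sl, name in zip(graph.block_slices(), graph.modality_names):
            coloring = nx.coloring.greedy_color(
                graph.nx_graph(name), strategy="largest_first"
            )
            for node, col in coloring.items():
                colors[sl.start + node] = col
        return [np.nonzero(colors == c)[0] for c in range(colors.max() + 1)]

    def phi_expanded(self, Phi: np.ndarray) -> np.ndarray:
        out = np.empty((self.p, Phi.shape[1]))
        for h, sl in enumerate(self.slices):
            out[sl] = Phi[h]
        return out


def _pseudo_data(ctx: ModelContext, state: MCMCState):
    """Working precisions omega and linear terms kappa, stacked (p, n).

    Gaussian rows: omega = rho_j, kappa = rho_j * x.  Logit rows (given the
    PG draws): omega = pg, kappa = x - b/2 where b is the PG shape.  In
    both cases the cell log-likelihood is kappa*mu - omega*mu^2/2 + const.
    """
    omega = np.empty((ctx.p, ctx.n))
    kappa = np.empty((ctx.p, ctx.n))
    for sl, mod, pg in zip(ctx.slices, ctx.modalities, state.aug.pg):
        if mod.family == "gaussian":
            rho = state.rho[sl][:, None]
            omega[sl] = np.broadcast_to(rho, mod.X.shape)
            kappa[sl] = rho * mod.X
        elif mod.family == "binomial":
            omega[sl] = pg
            kappa[sl] = mod.X - mod.trials[:, None] / 2.0
        else:  # negative binomial: b = r + x
            omega[sl] = pg
            kappa[sl] = (mod.X - mod.failures[:, None]) / 2.0
    return omega, kappa


def augment(state: MCMCState, ctx: ModelContext,
            rng: np.random.Generator) -> AugmentationState:
    """Draw all auxiliary variables from their exact full conditionals."""
    hyper = ctx.hyper
    rate_W = ctx.phi_expanded(state.Phi) * np.exp(state.A_mod)
    inv_s = rng.wald(
        rate_W / np.maximum(np.abs(state.W), _MIN_ABS), rate_W ** 2
    )
    s_W = 1.0 / np.maximum(inv_s, 1e-300)
    if ctx.p_y:
        rate_B = state.Lambda_y
        inv_sb = rng.wald(
            rate_B / np.maximum(np.abs(state.B), _MIN_ABS), rate_B ** 2
        )
        s_B = 1.0 / np.maximum(inv_sb, 1e-300)
    else:
        s_B = np.zeros((0, ctx.L))
    mu = state.m[:, None] + state.W @ state.Z
    pg: List[Optional[np.ndarray]] = []
    for sl, mod in zip(ctx.slices, ctx.modalities):
        if mod.family == "gaussian":
            pg.append(None)
        elif mod.family == "binomial":
            b = np.broadcast_to(mod.trials[:, None].astype(float), mod.X.shape)
            pg.append(random_polyagamma(b, mu[sl], rng))
        else:
            b = mod.failures[:, None] + mod.X
            pg.append(random_polyagamma(b, mu[sl], rng))
    return AugmentationState(s_W=s_W, s_B=s_B, pg=pg)


def _batched_gaussian_draw(P: np.ndarray, b: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """Draw x_k ~ N(P_k^{-1} b_k, P_k^{-1}) for stacked SPD systems.

    P is (k, d, d), b is (k, d); returns (k, d).
    """
    chol = np.linalg.cholesky(P)
    lower = np.linalg.solve(chol, b[..., None])
    mean = np.linalg.solve(np.swapaxes(chol, -1, -2), lower)[..., 0]
    noise = rng.standard_normal(b.shape)
    extra = np.linalg.solve(np.swapaxes(chol, -1, -2), noise[..., None])[..., 0]
    return mean + extra


def update_W(state: MCMCState, ctx: ModelContext,
             rng: np.random.Generator) -> None:
    """Gaussian full-conditional draw of every loading row."""
    omega, kappa = _pseudo_data(ctx, state)
    Z = state.Z
    t = kappa - omega * state.m[:, None]
    P = np.einsum("li,ji,ki->jlk", Z, omega, Z, optimize=True)
    idx = np.arange(ctx.L)
    P[:, idx, idx] += 1.0 / state.aug.s_W
    b = t @ Z.T
    state.W = _batched_gaussian_draw(P, b, rng)


def update_Z(state: MCMCState, ctx: ModelContext,
             rng: np.random.Generator) -> None:
    """Gaussian full-conditional draw of every latent-factor column."""
    omega, kappa = _pseudo_data(ctx, state)
    W = state.W
    t = kappa - omega * state.m[:, None]
    P = np.einsum("jl,ji,jk->ilk", W, omega, W, optimize=True)
    idx = np.arange(ctx.L)
    P[:, idx, idx] += 1.0
    b = (W.T @ t).T  # (n, L)
    if ctx.p_y:
        RB = state.rho_y[:, None] * state.B  # (p_y, L)
        P += (state.B.T @ RB)[None, :, :]
        b += (ctx.Y - state.beta0[:, None]).T @ RB
    state.Z = _batched_gaussian_draw(P, b, rng).T


def update_m_rho(state: MCMCState, ctx: ModelContext,
                 rng: np.random.Generator) -> None:
    """Conjugate draws of the location vector and Gaussian precisions."""
    omega, kappa = _pseudo_data(ctx, state)
    WZ = state.W @ state.Z
    prec = omega.sum(axis=1) + 1.0 / ctx.hyper.sigma_m2
    lin = np.sum(kappa - omega * WZ, axis=1)
    state.m = lin / prec + rng.standard_normal(ctx.p) / np.sqrt(prec)
    zeta = ctx.hyper.zeta
    for sl, mod in zip(ctx.slices, ctx.modalities):
        if mod.family != "gaussian":
            continue
        resid = mod.X - state.m[sl][:, None] - WZ[sl]
        shape = (zeta + ctx.n) / 2.0
        rate = (zeta + np.sum(resid ** 2, axis=1)) / 2.0
        state.rho[sl] = rng.gamma(shape, 1.0 / rate)
        mod.precision = state.rho[sl].copy()


def update_regression(state: MCMCState, ctx: ModelContext,
                      rng: np.random.Generator) -> None:
    """Joint conjugate draw of (beta0_j, beta_j) and gamma draw of rho_yj."""
    if not ctx.p_y:
        return
    Z = state.Z
    G = np.vstack([np.ones((1, ctx.n)), Z])  # (L+1, n)
    GGt = G @ G.T
    zeta = ctx.hyper.zeta
    for j in range(ctx.p_y):
        P = state.rho_y[j] * GGt
        P[0, 0] += 1.0 / ctx.hyper.sigma_b2
        P[np.arange(1, ctx.L + 1), np.arange(1, ctx.L + 1)] += \
            1.0 / state.aug.s_B[j]
        b = state.rho_y[j] * (G @ ctx.Y[j])
        draw = _batched_gaussian_draw(P[None], b[None], rng)[0]
        state.beta0[j] = draw[0]
        state.B[j] = draw[1:]
        resid = ctx.Y[j] - draw[0] - state.B[j] @ Z
        shape = (zeta + ctx.n) / 2.0
        rate = (zeta + np.sum(resid ** 2)) / 2.0
        state.rho_y[j] = rng.gamma(shape, 1.0 / rate)


def update_shrinkage(state: MCMCState, ctx: ModelContext,
                     rng: np.random.Generator) -> None:
    """Collapsed conjugate draws of Phi and Lambda_y given (W, B)."""
    hyper = ctx.hyper
    lam = np.exp(state.A_mod)
    absW = np.abs(state.W)
    for h, sl in enumerate(ctx.slices):
        shape = hyper.a_phi + (sl.stop - sl.start)
        rate = hyper.b_phi + np.sum(lam[sl] * absW[sl], axis=0)
        state.Phi[h] = rng.gamma(shape, 1.0 / rate)
    if ctx.p_y:
        shape = hyper.a_lambda + 1.0
        rate = hyper.b_lambda + np.abs(state.B)
        state.Lambda_y = rng.gamma(shape, 1.0 / rate)


def mh_update_A_mod(
    state: MCMCState,
    ctx: ModelContext,
    steps: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Adaptive random-walk Metropolis scan over entries of A_mod.

    Entries within one graph-coloring class (and across columns) have no
    direct coupling through Omega, so their acceptances are computed in
    parallel.  Returns the boolean (p, L) acceptance mask of this sweep.
    """
    hyper = ctx.hyper
    phi = ctx.phi_expanded(state.Phi)
    absW = np.abs(state.W)
    Om = state.Omega
    om_diag = np.diag(Om).copy()
    accepted = np.zeros((ctx.p, ctx.L), dtype=bool)
    A = state.A_mod
    for cls in ctx.color_classes:
        At = A - hyper.nu1
        V = Om[cls] @ At  # (|cls|, L) rows of Omega @ A_tilde
        delta = steps[cls] * rng.standard_normal((cls.size, ctx.L))
        a_old = A[cls]
        a_new = a_old + delta
        d_laplace = delta - phi[cls] * absW[cls] * (np.exp(a_new) -
                                                    np.exp(a_old))
        d_quad = 2.0 * delta * V + delta ** 2 * om_diag[cls, None]
        log_ratio = d_laplace - d_quad / (2.0 * hyper.nu2)
        acc = np.log(rng.random((cls.size, ctx.L))) < log_ratio
        A[cls] = np.where(acc, a_new, a_old)
        accepted[cls] = acc
    state.A_mod = A
    return accepted


def update_omega(state: MCMCState, ctx: ModelContext,
                 rng: np.random.Generator, n_sweeps: int = 1) -> None:
    """G-Wishart full-conditional refresh of the precision matrix."""
    state.Omega = ctx.omega_sampler.sample(
        state.A_mod, ctx.hyper.nu1, ctx.hyper.nu2, rng,
        K_init=state.Omega, n_sweeps=n_sweeps,
    )


# ---------------------------------------------------------------------------
# Chain driver
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Thinned posterior draws plus traces and MH diagnostics."""

    W: np.ndarray
    Z: np.ndarray
    m: np.ndarray
    rho: np.ndarray
    B: np.ndarray
    beta0: np.ndarray
    rho_y: np.ndarray
    Phi: np.ndarray
    Lambda_y: np.ndarray
    A_mod: np.ndarray
    Omega: List[sp.csr_matrix]
    log_posterior: np.ndarray
    log_likelihood: np.ndarray
    mh_acceptance_rate: float
    config: ChainConfig
    modality_names: List[str]
    block_sizes: List[int]

    @property
    def n_draws(self) -> int:
        return self.W.shape[0]


def _initial_state(ctx: ModelContext, rng: np.random.Generator,
                   W0: Optional[np.ndarray] = None,
                   m0: Optional[np.ndarray] = None) -> MCMCState:
    """Data-driven start: SVD of the (link-scale) centered data."""
    L, p, n = ctx.L, ctx.p, ctx.n
    Xw = np.empty((p, n))
    m = np.empty(p)
    for sl, mod in zip(ctx.slices, ctx.modalities):
        if mod.family == "gaussian":
            m[sl] = mod.X.mean(axis=1)
            Xw[sl] = mod.X - m[sl][:, None]
        elif mod.family == "binomial":
            rate = np.clip(
                mod.X.mean(axis=1) / mod.trials, 1.0 / (2 * ctx.n),
                1 - 1.0 / (2 * ctx.n),
            )
            m[sl] = np.log(rate / (1 - rate))
            Xw[sl] = (mod.X / mod.trials[:, None]) - rate[:, None]
        else:
            mean = np.maximum(mod.X.mean(axis=1), 0.5 / ctx.n)
            m[sl] = np.log(mean / mod.failures)
            Xw[sl] = np.log1p(mod.X) - np.log1p(mean)[:, None]
    if W0 is not None:
        W = np.asarray(W0, dtype=float).copy()
        m = np.asarray(m0, dtype=float).copy() if m0 is not None else m
        # fixed-loadings start: ridge projection of the working data
        WtW = W.T @ W + 0.1 * np.eye(L)
        Z = np.linalg.solve(WtW, W.T @ Xw)
    else:
        U, s, Vt = np.linalg.svd(Xw, full_matrices=False)
        k = min(L, s.size)
        Z = np.zeros((L, n))
        W = np.zeros((p, L))
        Z[:k] = Vt[:k] * np.sqrt(n)
        W[:, :k] = U[:, :k] * (s[:k] / np.sqrt(n))
    rho = np.full(p, np.nan)
    for sl, mod in zip(ctx.slices, ctx.modalities):
        if mod.family == "gaussian":
            resid = mod.X - m[sl][:, None] - W[sl] @ Z
            rho[sl] = 1.0 / np.maximum(resid.var(axis=1), 1e-6)
            mod.precision = rho[sl].copy()
    if ctx.p_y:
        G = np.vstack([np.ones((1, n)), Z])
        coef = np.linalg.solve(
            G @ G.T + np.eye(L + 1), G @ ctx.Y.T
        ).T  # (p_y, L+1)
        beta0, B = coef[:, 0].copy(), coef[:, 1:].copy()
        resid = ctx.Y - beta0[:, None] - B @ Z
        rho_y = 1.0 / np.maximum(resid.var(axis=1), 1e-6)
    else:
        beta0 = np.zeros(0)
        B = np.zeros((0, L))
        rho_y = np.zeros(0)
    return MCMCState(
        W=W, Z=Z, m=m, rho=rho, B=B, beta0=beta0, rho_y=rho_y,
        Phi=np.ones((ctx.H, L)),
        A_mod=np.full((p, L), ctx.hyper.nu1),
        Lambda_y=np.ones((ctx.p_y, L)),
        Omega=np.eye(p),
    )


def _outcome_state(ctx: ModelContext, state: MCMCState) -> Optional[OutcomeState]:
    if not ctx.p_y:
        return None
    return OutcomeState(Y=ctx.Y, B=state.B, beta0=state.beta0,
                        rho_y=state.rho_y, zeta_y=ctx.hyper.zeta)


def run_chain(
    modalities: Sequence[ModalityData],
    outcomes: Optional[np.ndarray],
    graph: FeatureGraph,
    hyper: Hyperparams,
    config: ChainConfig,
    L: int,
    fixed_W: Optional[np.ndarray] = None,
    fixed_m: Optional[np.ndarray] = None,
) -> PosteriorSamples:
    """Run the full MCMC and return thinned posterior draws.

    With ``fixed_W``/``fixed_m`` given, only the latent factors, Gaussian
    precisions and Pólya-Gamma variables are updated (the test-time
    prediction mode); all loading-side layers stay frozen.
    """
    rng = np.random.default_rng(config.seed)
    ctx = ModelContext(modalities, outcomes, graph, hyper, L)
    predict_mode = fixed_W is not None
    state = _initial_state(ctx, rng, W0=fixed_W, m0=fixed_m)
    steps = np.full((ctx.p, L), config.mh_step)
    adapt_until = config.n_burnin if config.adapt_window == 0 else \
        min(config.adapt_window, config.n_burnin)
    acc_acc = np.zeros((ctx.p, L))
    acc_count = 0
    mh_total = 0
    mh_accepted = 0

    T = config.n_stored
    store = {
        "W": np.empty((T, ctx.p, L)),
        "Z": np.empty((T, L, ctx.n)),
        "m": np.empty((T, ctx.p)),
        "rho": np.empty((T, ctx.p)),
        "B": np.empty((T, ctx.p_y, L)),
        "beta0": np.empty((T, ctx.p_y)),
        "rho_y": np.empty((T, ctx.p_y)),
        "Phi": np.empty((T, ctx.H, L)),
        "Lambda_y": np.empty((T, ctx.p_y, L)),
        "A_mod": np.empty((T, ctx.p, L)),
    }
    omegas: List[sp.csr_matrix] = []
    lp_trace = np.empty(T)
    ll_trace = np.empty(T)
    t_store = 0

    for it in range(config.n_iter):
        state.aug = augment(state, ctx, rng)
        if not predict_mode:
            update_W(state, ctx, rng)
        update_Z(state, ctx, rng)
        if predict_mode:
            _update_rho_only(state, ctx, rng)
        else:
            update_m_rho(state, ctx, rng)
            update_regression(state, ctx, rng)
            update_shrinkage(state, ctx, rng)
            acc = mh_update_A_mod(state, ctx, steps, rng)
            mh_total += acc.size
            mh_accepted += int(acc.sum())
            acc_acc += acc
            acc_count += 1
            if it < adapt_until and acc_count == 25:
                rate = acc_acc / acc_count
                steps *= np.exp(np.clip(rate - 0.3, -0.5, 0.5))
                steps = np.clip(steps, 1e-3, 10.0)
                acc_acc[:] = 0.0
                acc_count = 0
            if config.sample_omega:
                update_omega(state, ctx, rng,
                             n_sweeps=config.omega_inner_sweeps)

        if config.nan_check_every and (it + 1) % config.nan_check_every == 0:
            ll = loglik_full(ctx.modalities, state.factor_state(),
                             _outcome_state(ctx, state))
            if not np.isfinite(ll):
                raise RuntimeError(
                    f"divergent log-likelihood at sweep {it + 1}: {ll!r}; "
                    f"|W|max={np.abs(state.W).max():.3g}, "
                    f"|Z|max={np.abs(state.Z).max():.3g}"
                )

        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0 \
                and t_store < T:
            for key in ("W", "Z", "m", "rho", "B", "beta0", "rho_y", "Phi",
                        "Lambda_y", "A_mod"):
                store[key][t_store] = getattr(state, key)
            if config.store_omega:
                omegas.append(sp.csr_matrix(state.Omega))
            shrink = ShrinkageState(Phi=state.Phi, A_mod=state.A_mod,
                                    Lambda_y=np.maximum(state.Lambda_y, 1e-300)
                                    if ctx.p_y else np.ones((0, L)))
            ll_trace[t_store] = loglik_full(
                ctx.modalities, state.factor_state(), _outcome_state(ctx, state)
            )
            lp_trace[t_store] = joint_log_posterior(
                ctx.modalities, state.factor_state(), shrink, state.Omega,
                ctx.graph, hyper, _outcome_state(ctx, state),
            )
            t_store += 1

    return PosteriorSamples(
        W=store["W"], Z=store["Z"], m=store["m"], rho=store["rho"],
        B=store["B"], beta0=store["beta0"], rho_y=store["rho_y"],
        Phi=store["Phi"], Lambda_y=store["Lambda_y"], A_mod=store["A_mod"],
        Omega=omegas, log_posterior=lp_trace, log_likelihood=ll_trace,
        mh_acceptance_rate=(mh_accepted / mh_total) if mh_total else float("nan"),
        config=config,
        modality_names=[m.name for m in modalities],
        block_sizes=[m.p for m in modalities],
    )


def _update_rho_only(state: MCMCState, ctx: ModelContext,
                     rng: np.random.Generator) -> None:
    WZ = state.W @ state.Z
    zeta = ctx.hyper.zeta
    for sl, mod in zip(ctx.slices, ctx.modalities):
        if mod.family != "gaussian":
            continue
        resid = mod.X - state.m[sl][:, None] - WZ[sl]
        shape = (zeta + ctx.n) / 2.0
        rate = (zeta + np.sum(resid ** 2, axis=1)) / 2.0
        state.rho[sl] = rng.gamma(shape, 1.0 / rate)
        mod.precision = state.rho[sl].copy()


def posterior_mean_mu(samples: PosteriorSamples):
    """Posterior means of the modality and outcome mean structures.

    mu_hat = (1/T) sum_t (m_t 1' + W_t Z_t);
    mu_y_hat = (1/T) sum_t (beta0_t 1' + B_t Z_t).
    """
    T = samples.n_draws
    if T == 0:
        raise ValidationError("no stored draws")
    p, n = samples.W.shape[1], samples.Z.shape[2]
    mu = np.zeros((p, n))
    for t in range(T):
        mu += samples.m[t][:, None] + samples.W[t] @ samples.Z[t]
    mu /= T
    p_y = samples.B.shape[1]
    if p_y:
        mu_y = np.zeros((p_y, n))
        for t in range(T):
            mu_y += samples.beta0[t][:, None] + samples.B[t] @ samples.Z[t]
        mu_y /= T
    else:
        mu_y = np.zeros((0, n))
    return mu, mu_y


# ---------------------------------------------------------------------------
# Forward simulation helpers (prior draws and data regeneration), used by
# joint-distribution (Geweke-style) correctness checks.
# ---------------------------------------------------------------------------

def sample_prior_state(ctx: ModelContext,
                       rng: np.random.Generator) -> MCMCState:
    """One exact draw of all parameters from the prior."""
    hyper = ctx.hyper
    p, L, n = ctx.p, ctx.L, ctx.n
    Omega = ctx.omega_sampler.sample(None, 0.0, 1.0, rng, n_sweeps=200)
    A = np.empty((p, L))
    chol = np.linalg.cholesky(Omega)
    for l in range(L):
        noise = rng.standard_normal(p)
        A[:, l] = hyper.nu1 + np.sqrt(hyper.nu2) * \
            np.linalg.solve(chol.T, noise)
    Phi = rng.gamma(hyper.a_phi, 1.0 / hyper.b_phi, size=(ctx.H, L))
    rate_W = ctx.phi_expanded(Phi) * np.exp(A)
    W = rng.laplace(0.0, 1.0 / rate_W)
    Z = rng.standard_normal((L, n))
    m = rng.standard_normal(p) * np.sqrt(hyper.sigma_m2)
    rho = np.full(p, np.nan)
    rho[ctx.gaussian_mask] = rng.gamma(
        hyper.zeta / 2.0, 2.0 / hyper.zeta, size=int(ctx.gaussian_mask.sum())
    )
    if ctx.p_y:
        Lambda_y = rng.gamma(hyper.a_lambda, 1.0 / hyper.b_lambda,
                             size=(ctx.p_y, L))
        B = rng.laplace(0.0, 1.0 / Lambda_y)
        beta0 = rng.standard_normal(ctx.p_y) * np.sqrt(hyper.sigma_b2)
        rho_y = rng.gamma(hyper.zeta / 2.0, 2.0 / hyper.zeta, size=ctx.p_y)
    else:
        Lambda_y = np.ones((0, L))
        B = np.zeros((0, L))
        beta0 = np.zeros(0)
        rho_y = np.zeros(0)
    return MCMCState(W=W, Z=Z, m=m, rho=rho, B=B, beta0=beta0, rho_y=rho_y,
                     Phi=Phi, A_mod=A, Lambda_y=Lambda_y, Omega=Omega)


def resample_observations(state: MCMCState, ctx: ModelContext,
                          rng: np.random.Generator) -> None:
    """Redraw X (and Y) from the likelihood given the current parameters."""
    mu = state.m[:, None] + state.W @ state.Z
    for sl, mod in zip(ctx.slices, ctx.modalities):
        if mod.family == "gaussian":
            sd = 1.0 / np.sqrt(state.rho[sl])[:, None]
            mod.X = mu[sl] + sd * rng.standard_normal(mod.X.shape)
        elif mod.family == "binomial":
            prob = 1.0 / (1.0 + np.exp(-mu[sl]))
            mod.X = rng.binomial(mod.trials[:, None], prob).astype(float)
        else:
            prob = 1.0 / (1.0 + np.exp(-mu[sl]))
            mod.X = rng.negative_binomial(
                mod.failures[:, None], 1.0 - prob
            ).astype(float)
    if ctx.p_y:
        mu_y = state.beta0[:, None] + state.B @ state.Z
        sd = 1.0 / np.sqrt(state.rho_y)[:, None]
        ctx.Y[...] = mu_y + sd * rng.standard_normal(ctx.Y.shape)
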