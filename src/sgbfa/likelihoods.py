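"""Likelihood evaluation and the joint log-posterior.

Every modality is linked to the shared low-rank structure through
``mu = m 1' + W Z``: for Gaussian blocks mu is the mean, for binomial and
negative-binomial blocks mu is the log-odds of the success probability.
Binomial/negative-binomial normalizing constants (log-choose terms) are
included so stored likelihood values are comparable across models with a
different number of factors (needed for DIC).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, betaln

from .data import (
    FactorState,
    Hyperparams,
    ModalityData,
    OutcomeState,
    ShrinkageState,
    ValidationError,
    block_slices,
)

__all__ = [
    "linearize",
    "loglik_modality",
    "loglik_outcomes",
    "loglik_full",
    "joint_log_posterior",
]


def linearize(factor_state: FactorState) -> np.ndarray:
    """Return the stacked linear predictor mu = m 1' + W Z  (p x n)."""
    return factor_state.m[:, None] + factor_state.W @ factor_state.Z


def _log1pexp(x: np.ndarray) -> np.ndarray:
    """log(1 + e^x), overflow-safe."""
    out = np.empty_like(x, dtype=float)
    pos = x > 0
    out[pos] = x[pos] + np.log1p(np.exp(-x[pos]))
    out[~pos] = np.log1p(np.exp(x[~pos]))
    return out


def loglik_modality(data: ModalityData, mu_block: np.ndarray) -> float:
    """Log-likelihood of one modality given its linear predictor block.

    Gaussian: sum of 0.5*log(rho/2pi) - rho*(x-mu)^2/2.
    Binomial: log C(n,x) + mu*x - n*log(1+e^mu).
    Negative binomial: log C(r+x-1,x) + mu*x - (r+x)*log(1+e^mu).
    """
    mu = np.asarray(mu_block, dtype=float)
    if mu.shape != data.X.shape:
        raise ValidationError(
            f"mu block shape {mu.shape} != data shape {data.X.shape}"
        )
    X = data.X
    if data.family == "gaussian":
        rho = data.precision
        if rho is None:
            raise ValidationError(
                f"modality {data.name!r}: gaussian precision not set"
            )
        n = X.shape[1]
        return float(
            0.5 * n * np.sum(np.log(rho / (2.0 * np.pi)))
            - 0.5 * np.sum(rho[:, None] * (X - mu) ** 2)
        )
    if data.family == "binomial":
        nt = data.trials[:, None].astype(float)
        const = gammaln(nt + 1) - gammaln(X + 1) - gammaln(nt - X + 1)
        return float(np.sum(const + mu * X - nt * _log1pexp(mu)))
    # negative binomial
    r = data.failures[:, None]
    const = -betaln(r, X + 1) - np.log(X + r)
    return float(np.sum(const + mu * X - (r + X) * _log1pexp(mu)))


def loglik_outcomes(outcome_state: OutcomeState, Z: np.ndarray) -> float:
    """Gaussian log-likelihood of Y given beta0 + B Z, per-outcome precision."""
    if outcome_state.p_y == 0:
        return 0.0
    rho = outcome_state.rho_y
    if np.any(rho <= 0):
        raise ValidationError("rho_y must be positive")
    mu_y = outcome_state.beta0[:, None] + outcome_state.B @ Z
    resid = outcome_state.Y - mu_y
    n = Z.shape[1]
    return float(
        0.5 * n * np.sum(np.log(rho / (2.0 * np.pi)))
        - 0.5 * np.sum(rho[:, None] * resid ** 2)
    )


def loglik_full(
    modalities: Sequence[ModalityData],
    factor_state: FactorState,
    outcome_state: Optional[OutcomeState] = None,
) -> float:
    """Total data log-likelihood l(D, U): all modality blocks plus outcomes."""
    mu = linearize(factor_state)
    total = 0.0
    for sl, mod in zip(block_slices(modalities), modalities):
        total += loglik_modality(mod, mu[sl])
    if outcome_state is not None:
        total += loglik_outcomes(outcome_state, factor_state.Z)
    return total


def joint_log_posterior(
    modalities: Sequence[ModalityData],
    factor_state: FactorState,
    shrinkage: ShrinkageState,
    Omega,
    graph,
    hyper: Hyperparams,
    outcome_state: Optional[OutcomeState] = None,
) -> float:
    """Unnormalized joint log-posterior of all parameter blocks.

    Returns -inf when Omega is incompatible with the feature graph.  The
    graph-constrained Wishart term is evaluated up to its (intractable)
    normalizing constant; all other prior terms are normalized densities.
    """
    from . import priors

    Om = np.asarray(Omega, dtype=float)
    lp_omega = priors.logprior_omega(Om, graph, hyper.eta, hyper.epsilon)
    if not np.isfinite(lp_omega):
        return -np.inf

    total = loglik_full(modalities, factor_state, outcome_state)
    slices = block_slices(modalities)
    total += priors.logprior_laplace_W(
        factor_state.W, shrinkage.Lambda_mod, shrinkage.Phi,
        [sl for sl in slices],
    )
    total += priors.logprior_phi(shrinkage.Phi, hyper.a_phi, hyper.b_phi)
    total += priors.logprior_A_mod(shrinkage.A_mod, Om, hyper.nu1, hyper.nu2)
    total += lp_omega
    if outcome_state is not None and outcome_state.p_y > 0:
        total += priors.logprior_laplace_B(outcome_state.B, shrinkage.Lambda_y)
        total += priors.logprior_lambda_y(
            shrinkage.Lambda_y, hyper.a_lambda, hyper.b_lambda
        )
        beta0 = outcome_state.beta0
        rho_y = outcome_state.rho_y
        zeta_y = outcome_state.zeta_y
    else:
        beta0 = np.zeros(0)
        rho_y = np.zeros(0)
        zeta_y = np.zeros(0)
    total += priors.logprior_nuisance(
        factor_state.m, factor_state.Z, beta0, rho_y, hyper, zeta_y=zeta_y
    )
    for mod in modalities:
        if mod.family == "gaussian":
            total += priors.logprior_gamma_precisions(
                mod.precision, np.full(mod.p, hyper.zeta)
            )
    return float(total)
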