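"""Log-density evaluation for every prior layer of the model.

All priors are evaluated as normalized log-densities except the
graph-constrained Wishart on Omega, whose normalizing constant under the
graph restriction is intractable; there the unnormalized value is returned
(only differences of it are ever used, in Metropolis ratios).

Conventions
-----------
* Laplace priors on loadings/coefficients carry the normalized constant
  ``-log 2`` per entry, so ``exp(logprior)`` integrates to one along any
  single coordinate.
* ``A_mod = log Lambda_mod`` columns are jointly Gaussian with mean
  ``nu1 * 1`` and covariance ``nu2 * Omega^{-1}``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .data import Hyperparams, ValidationError

__all__ = [
    "logprior_laplace_W",
    "logprior_laplace_B",
    "logprior_phi",
    "logprior_lambda_y",
    "logprior_A_mod",
    "logprior_omega",
    "omega_prior_mode",
    "logprior_nuisance",
    "logprior_gamma_precisions",
    "expand_phi",
]

_LOG2 = np.log(2.0)


def expand_phi(Phi: np.ndarray, slices: Sequence[slice], p: int) -> np.ndarray:
    """Expand the H x L modality-rate matrix to a p x L per-feature matrix."""
    Phi = np.asarray(Phi, dtype=float)
    out = np.empty((p, Phi.shape[1]))
    for h, sl in enumerate(slices):
        out[sl] = Phi[h]
    return out


def logprior_laplace_W(
    W: np.ndarray,
    Lambda_mod: np.ndarray,
    Phi: np.ndarray,
    slices: Optional[Sequence[slice]] = None,
) -> float:
    """Normalized Laplace log-prior of the loadings.

    Each entry w_jl^(h) ~ Laplace(rate = phi_l^(h) * lambda_jl^(h)):
    log density = log(rate) - log 2 - rate*|w|.
    ``Phi`` may be given per modality (H x L, with ``slices``) or already
    expanded per feature (p x L).
    """
    W = np.asarray(W, dtype=float)
    lam = np.asarray(Lambda_mod, dtype=float)
    Phi = np.asarray(Phi, dtype=float)
    if Phi.shape != W.shape:
        if slices is None:
            raise ValidationError("Phi shape mismatch and no block slices given")
        Phi = expand_phi(Phi, slices, W.shape[0])
    if np.any(lam <= 0) or np.any(Phi <= 0):
        raise ValidationError("lambda and phi must be strictly positive")
    rate = Phi * lam
    return float(np.sum(np.log(rate) - _LOG2 - rate * np.abs(W)))


def logprior_laplace_B(B: np.ndarray, Lambda_y: np.ndarray) -> float:
    """Normalized Laplace log-prior of regression coefficients (rate lambda_y)."""
    B = np.asarray(B, dtype=float)
    lam = np.asarray(Lambda_y, dtype=float)
    if np.any(lam <= 0):
        raise ValidationError("Lambda_y must be strictly positive")
    return float(np.sum(np.log(lam) - _LOG2 - lam * np.abs(B)))


def _gamma_logpdf_sum(x: np.ndarray, shape, rate) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return 0.0
    if np.any(x < 0):
        raise ValidationError("gamma-distributed quantities must be >= 0")
    shape = np.broadcast_to(np.asarray(shape, dtype=float), x.shape)
    rate = np.broadcast_to(np.asarray(rate, dtype=float), x.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        logx = np.where(x > 0, np.log(np.maximum(x, 1e-300)), -np.inf)
        terms = shape * np.log(rate) - gammaln(shape) \
            + (shape - 1.0) * logx - rate * x
        # shape == 1 at x == 0 is the exponential boundary: density = rate
        boundary = (x == 0) & (shape == 1.0)
        terms = np.where(boundary, np.log(rate), terms)
    return float(np.sum(terms))


def logprior_phi(Phi: np.ndarray, a_phi: float, b_phi: float) -> float:
    """i.i.d. Gamma(a_phi, b_phi) log-prior over the modality-level rates."""
    return _gamma_logpdf_sum(Phi, a_phi, b_phi)


def logprior_lambda_y(Lambda_y: np.ndarray, a_lambda: float,
                      b_lambda: float) -> float:
    """i.i.d. Gamma(a_lambda, b_lambda) log-prior over the outcome rates."""
    return _gamma_logpdf_sum(Lambda_y, a_lambda, b_lambda)


def logprior_A_mod(A_mod: np.ndarray, Omega: np.ndarray, nu1: float,
                   nu2: float) -> float:
    """Graph-coupled Gaussian log-prior of the log feature-shrinkage matrix.

    Columns of A_mod are i.i.d. N(nu1*1, nu2 * Omega^{-1}); the value is the
    fully normalized multivariate-normal log-density summed over columns.
    """
    A = np.asarray(A_mod, dtype=float)
    Om = np.asarray(Omega, dtype=float)
    p, L = A.shape
    try:
        chol = np.linalg.cholesky(Om)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("Omega must be positive definite") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    At = A - nu1
    quad = np.sum(At * (Om @ At))
    return float(
        -0.5 * p * L * np.log(2.0 * np.pi * nu2)
        + 0.5 * L * logdet
        - quad / (2.0 * nu2)
    )


def logprior_omega(Omega: np.ndarray, graph, eta: float,
                   epsilon: float) -> float:
    """Unnormalized graph-constrained Wishart log-prior of Omega.

    (eta(1+eps)/2) log|Omega| - (eta/2) tr((11' + eps I) Omega) on the set of
    symmetric PD matrices whose off-diagonal support lies within the graph's
    edge set; -inf otherwise.  ``graph`` may be None to skip the support
    check (unconstrained evaluation).
    """
    Om = np.asarray(Omega, dtype=float)
    if Om.ndim != 2 or Om.shape[0] != Om.shape[1]:
        raise ValidationError("Omega must be square")
    if not np.allclose(Om, Om.T, atol=1e-10):
        raise ValidationError("Omega must be symmetric")
    if graph is not None:
        from .graph import check_compatibility

        if not check_compatibility(Om, graph):
            return -np.inf
    sign, logdet = np.linalg.slogdet(Om)
    if sign <= 0:
        return -np.inf
    p = Om.shape[0]
    # tr((11' + eps I) Omega) = sum(Omega) + eps * tr(Omega)
    tr_term = float(np.sum(Om) + epsilon * np.trace(Om))
    return float(0.5 * eta * (1.0 + epsilon) * logdet - 0.5 * eta * tr_term)


def omega_prior_mode(p: int, epsilon: float) -> np.ndarray:
    """Mode of the unconstrained Omega prior: inverse of (11'+eps I)/(1+eps).

    Computed via Sherman-Morrison:  ((11' + eps I)/(1+eps))^{-1}
      = (1+eps)/eps * (I - 11'/(eps + p)).
    """
    if p < 1 or epsilon <= 0:
        raise ValidationError("need p >= 1 and epsilon > 0")
    eye = np.eye(p)
    ones = np.ones((p, p))
    return (1.0 + epsilon) / epsilon * (eye - ones / (epsilon + p))


def logprior_nuisance(
    m: np.ndarray,
    Z: np.ndarray,
    beta0: np.ndarray,
    rho_y: Optional[np.ndarray],
    hyper: Hyperparams,
    zeta_y=None,
) -> float:
    """Gaussian priors for m, Z, beta0 and gamma priors for rho_y.

    m ~ N(0, sigma_m^2 I);  Z entries ~ N(0,1);  beta0 ~ N(0, sigma_b^2 I);
    rho_yj ~ Gamma(zeta_j/2, zeta_j/2).
    """
    m = np.asarray(m, dtype=float)
    Z = np.asarray(Z, dtype=float)
    beta0 = np.asarray(beta0, dtype=float)
    total = -0.5 * m.size * np.log(2.0 * np.pi * hyper.sigma_m2) \
        - 0.5 * np.sum(m ** 2) / hyper.sigma_m2
    total += -0.5 * Z.size * np.log(2.0 * np.pi) - 0.5 * np.sum(Z ** 2)
    total += -0.5 * beta0.size * np.log(2.0 * np.pi * hyper.sigma_b2) \
        - 0.5 * np.sum(beta0 ** 2) / hyper.sigma_b2
    if rho_y is not None and np.asarray(rho_y).size:
        zeta = hyper.zeta if zeta_y is None else zeta_y
        total += logprior_gamma_precisions(np.asarray(rho_y), zeta)
    return float(total)


def logprior_gamma_precisions(rho: Optional[np.ndarray], zeta) -> float:
    """Gamma(zeta/2, zeta/2) log-prior for a vector of precisions."""
    if rho is None:
        return 0.0
    rho = np.asarray(rho, dtype=float)
    if rho.size == 0:
        return 0.0
    zeta = np.broadcast_to(np.asarray(zeta, dtype=float), rho.shape)
    return _gamma_logpdf_sum(rho, zeta / 2.0, zeta / 2.0)
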