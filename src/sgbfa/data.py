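"""Domain containers for the multi-modal factor model.

The model represents each omics block ("modality") as a feature-by-sample
matrix with a likelihood family (Gaussian, binomial or negative binomial),
linked to a shared low-rank mean structure ``mu = m 1' + W Z``.  Containers
here are thin, validated dataclasses; all numerics live in the sibling
modules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ModalityData",
    "FactorState",
    "OutcomeState",
    "ShrinkageState",
    "Hyperparams",
    "ChainConfig",
    "ValidationError",
]

FAMILIES = ("gaussian", "binomial", "negative_binomial")


class ValidationError(ValueError):
    """Raised when inputs violate a model-contract precondition."""


@dataclass
class ModalityData:
    """One omics block X^(h) together with its likelihood family.

    Parameters
    ----------
    name : str
        Modality label (e.g. ``"expression"``).
    X : ndarray of shape (p_h, n)
        Feature-by-sample observations.
    family : {"gaussian", "binomial", "negative_binomial"}
    trials : ndarray of shape (p_h,), optional
        Per-feature binomial trial counts ``n_j >= 1``.  Binary data is
        binomial with ``trials == 1``.  Genotype dosages coded {0,1,2} are
        treated as binomial with ``trials == 2`` (minor-allele counts).
    failures : ndarray of shape (p_h,), optional
        Per-feature negative-binomial failure parameters ``r_j > 0``.
    precision : ndarray of shape (p_h,), optional
        Per-feature Gaussian precisions ``rho_j > 0`` (sampled during MCMC;
        may be left None before fitting).
    feature_ids : sequence of str, optional
        Row labels; defaults to ``name:0..p_h-1``.
    """

    name: str
    X: np.ndarray
    family: str
    trials: Optional[np.ndarray] = None
    failures: Optional[np.ndarray] = None
    precision: Optional[np.ndarray] = None
    feature_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValidationError(f"modality {self.name!r}: X must be 2-D")
        if self.family not in FAMILIES:
            raise ValidationError(
                f"modality {self.name!r}: unknown family {self.family!r}"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValidationError(
                f"modality {self.name!r}: X contains non-finite entries "
                "(missing values are not supported)"
            )
        p = self.p
        if self.family == "binomial":
            if self.trials is None:
                raise ValidationError(
                    f"modality {self.name!r}: binomial family requires trials"
                )
            self.trials = np.asarray(self.trials)
            if self.trials.shape != (p,) or np.any(self.trials < 1):
                raise ValidationError(
                    f"modality {self.name!r}: trials must be (p_h,) with n_j >= 1"
                )
            if self.failures is not None or self.precision is not None:
                raise ValidationError(
                    f"modality {self.name!r}: only trials may be set for binomial"
                )
            bad = (self.X < 0) | (self.X > self.trials[:, None])
            if np.any(bad) or np.any(self.X != np.round(self.X)):
                raise ValidationError(
                    f"modality {self.name!r}: binomial entries must be integers "
                    "in {0,...,n_j}"
                )
        elif self.family == "negative_binomial":
            if self.failures is None:
                raise ValidationError(
                    f"modality {self.name!r}: negative_binomial requires failures"
                )
            self.failures = np.asarray(self.failures, dtype=float)
            if self.failures.shape != (p,) or np.any(self.failures <= 0):
                raise ValidationError(
                    f"modality {self.name!r}: failures must be (p_h,) positive"
                )
            if self.trials is not None or self.precision is not None:
                raise ValidationError(
                    f"modality {self.name!r}: only failures may be set for "
                    "negative_binomial"
                )
            if np.any(self.X < 0) or np.any(self.X != np.round(self.X)):
                raise ValidationError(
                    f"modality {self.name!r}: negative-binomial entries must be "
                    "nonnegative integers"
                )
        else:  # gaussian
            if self.trials is not None or self.failures is not None:
                raise ValidationError(
                    f"modality {self.name!r}: gaussian takes no trials/failures"
                )
            if self.precision is not None:
                self.precision = np.asarray(self.precision, dtype=float)
                if self.precision.shape != (p,) or np.any(self.precision <= 0):
                    raise ValidationError(
                        f"modality {self.name!r}: precision must be (p_h,) positive"
                    )
        if self.feature_ids is None:
            self.feature_ids = [f"{self.name}:{j}" for j in range(p)]
        elif len(self.feature_ids) != p:
            raise ValidationError(
                f"modality {self.name!r}: {len(self.feature_ids)} feature ids "
                f"for {p} rows"
            )

    @property
    def p(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    def with_precision(self, rho: np.ndarray) -> "ModalityData":
        return replace(self, precision=np.asarray(rho, dtype=float))


def check_shared_n(modalities: Sequence[ModalityData]) -> int:
    """Validate that all modalities share one sample dimension; return n."""
    if not modalities:
        raise ValidationError("at least one modality is required")
    n = modalities[0].n
    for mod in modalities[1:]:
        if mod.n != n:
            raise ValidationError(
                f"modality {mod.name!r} has n={mod.n}, expected {n}"
            )
    return n


def block_slices(modalities: Sequence[ModalityData]) -> list[slice]:
    """Row slices of the stacked feature dimension, one per modality."""
    out, start = [], 0
    for mod in modalities:
        out.append(slice(start, start + mod.p))
        start += mod.p
    return out


@dataclass
class FactorState:
    """Current values of the low-rank mean decomposition mu = m 1' + W Z."""

    W: np.ndarray  # (p, L) stacked loading blocks
    Z: np.ndarray  # (L, n) latent factors
    m: np.ndarray  # (p,) location vector

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if self.W.ndim != 2 or self.Z.ndim != 2 or self.m.ndim != 1:
            raise ValidationError("W must be (p,L), Z (L,n), m (p,)")
        if self.W.shape[1] != self.Z.shape[0]:
            raise ValidationError(
                f"W has L={self.W.shape[1]} but Z has L={self.Z.shape[0]}"
            )
        if self.m.shape[0] != self.W.shape[0]:
            raise ValidationError("m length must match rows of W")
        for name, arr in (("W", self.W), ("Z", self.Z), ("m", self.m)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite entries")

    @property
    def L(self) -> int:
        return self.W.shape[1]

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def n(self) -> int:
        return self.Z.shape[1]


@dataclass
class OutcomeState:
    """Supervised regression layer: y_j = beta_j0 + Z' beta_j + eps."""

    Y: np.ndarray  # (p_y, n)
    B: np.ndarray  # (p_y, L)
    beta0: np.ndarray  # (p_y,)
    rho_y: np.ndarray  # (p_y,) outcome precisions 1/sigma_yj^2
    zeta_y: np.ndarray | float = 1.0  # Gamma(zeta/2, zeta/2) prior control

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.rho_y = np.asarray(self.rho_y, dtype=float)
        py = self.Y.shape[0]
        if self.B.shape[0] != py or self.beta0.shape != (py,) or \
                self.rho_y.shape != (py,):
            raise ValidationError("outcome state dimensions inconsistent")
        if np.any(self.rho_y <= 0):
            raise ValidationError("rho_y must be strictly positive")
        self.zeta_y = np.broadcast_to(
            np.asarray(self.zeta_y, dtype=float), (py,)
        ).copy()

    @property
    def p_y(self) -> int:
        return self.Y.shape[0]


@dataclass
class ShrinkageState:
    """Two-level shrinkage state.

    ``Phi`` holds modality-level rates phi_l^(h) (H x L); ``A_mod`` is the
    log of the feature-level shrinkage matrix Lambda_mod (p x L), whose
    columns are coupled through the graph precision Omega; ``Lambda_y``
    holds the outcome-coefficient rates (p_y x L).
    """

    Phi: np.ndarray
    A_mod: np.ndarray
    Lambda_y: np.ndarray

    def __post_init__(self) -> None:
        self.Phi = np.asarray(self.Phi, dtype=float)
        self.A_mod = np.asarray(self.A_mod, dtype=float)
        self.Lambda_y = np.asarray(self.Lambda_y, dtype=float)
        if np.any(self.Phi <= 0):
            raise ValidationError("Phi entries must be strictly positive")
        if np.any(self.Lambda_y <= 0):
            raise ValidationError("Lambda_y entries must be strictly positive")
        if not np.all(np.isfinite(self.A_mod)):
            raise ValidationError("A_mod must be finite")

    @property
    def Lambda_mod(self) -> np.ndarray:
        return np.exp(self.A_mod)


@dataclass
class Hyperparams:
    """Fixed prior hyperparameters.

    nu1, nu2 : prior mean / variance scale of the log feature-shrinkage
        (tunable via DIC grid search).
    a_phi, b_phi : gamma shape/rate for the modality-level rates phi.
    a_lambda, b_lambda : gamma shape/rate for the outcome rates lambda_y.
    eta, epsilon : constrained-Wishart confidence and correlation control
        (eta=10, epsilon=0.2 are the fixed working values).
    sigma_m2, sigma_b2 : prior variances for m and beta0.
    zeta : shape/rate control of the Gamma(zeta/2, zeta/2) precision priors
        for Gaussian features and outcomes.
    """

    nu1: float = 0.0
    nu2: float = 1.0
    a_phi: float = 1.0
    b_phi: float = 1.0
    a_lambda: float = 1.0
    b_lambda: float = 1.0
    eta: float = 10.0
    epsilon: float = 0.2
    sigma_m2: float = 100.0
    sigma_b2: float = 100.0
    zeta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("nu2", "a_phi", "b_phi", "a_lambda", "b_lambda",
                     "eta", "epsilon", "sigma_m2", "sigma_b2", "zeta"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"hyperparameter {name} must be positive")


@dataclass
class ChainConfig:
    """MCMC run configuration."""

    n_iter: int = 5000
    n_burnin: int = 2500
    thin: int = 5
    seed: int = 0
    mh_step: float = 0.5
    adapt_window: int = 0  # 0 -> adapt throughout burn-in
    omega_inner_sweeps: int = 1
    store_omega: bool = True
    sample_omega: bool = True
    nan_check_every: int = 100

    def __post_init__(self) -> None:
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValidationError("need n_iter > n_burnin >= 0")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin
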