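"""Evaluation utilities: reconstruction error, prediction and factor typing."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .data import ChainConfig, Hyperparams, ModalityData, ValidationError
from .graph import FeatureGraph
from .sampler import run_chain

__all__ = [
    "rre",
    "mse",
    "classify_factors",
    "predict_outcomes",
    "EvalReport",
]

FACTOR_TYPES = ("all_shared", "subset_shared", "specific", "null")


@dataclass
class EvalReport:
    """Bundle of evaluation outputs for one fitted scenario."""

    rre: Optional[float]
    mse_per_outcome: Optional[np.ndarray]
    factor_types: List[str]
    active_modality_sets: List[Tuple[int, ...]]

    def to_dict(self) -> dict:
        return {
            "rre": self.rre,
            "mse_per_outcome": None if self.mse_per_outcome is None
            else [float(v) for v in self.mse_per_outcome],
            "factor_types": list(self.factor_types),
            "active_modality_sets": [list(s) for s in
                                     self.active_modality_sets],
        }


def rre(mu_hat: np.ndarray, mu_true: np.ndarray) -> float:
    """Relative reconstruction error ||mu_hat - mu|| / ||mu|| (Frobenius)."""
    mu_hat = np.asarray(mu_hat, dtype=float)
    mu_true = np.asarray(mu_true, dtype=float)
    if mu_hat.shape != mu_true.shape:
        raise ValidationError("shape mismatch in rre")
    denom = np.linalg.norm(mu_true)
    if denom == 0:
        raise ValidationError("true mean structure has zero norm")
    return float(np.linalg.norm(mu_hat - mu_true) / denom)


def mse(Y: np.ndarray, Y_hat: np.ndarray) -> np.ndarray:
    """Per-outcome mean squared prediction error (vector of length p_y)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Y_hat = np.atleast_2d(np.asarray(Y_hat, dtype=float))
    if Y.shape != Y_hat.shape:
        raise ValidationError("shape mismatch in mse")
    return np.mean((Y - Y_hat) ** 2, axis=1)


def classify_factors(
    W_samples: np.ndarray,
    block_sizes: Sequence[int],
    tau: float = 0.1,
) -> Tuple[List[str], List[Tuple[int, ...]]]:
    """Label each factor by its active modality set from posterior draws.

    Modality block h of factor l is declared active when the posterior mean
    of its per-entry loading magnitude, mean_j E|w_jl^(h)|, exceeds
    ``tau`` times the global per-entry mean |w|.  Labels: active in all
    modalities -> all_shared; in several -> subset_shared; in one ->
    specific; in none -> null.
    """
    W_samples = np.asarray(W_samples, dtype=float)
    if W_samples.ndim == 2:
        W_samples = W_samples[None]
    T, p, L = W_samples.shape
    if sum(block_sizes) != p:
        raise ValidationError("block sizes do not sum to p")
    absmean = np.mean(np.abs(W_samples), axis=0)  # (p, L)
    global_mean = float(absmean.mean())
    H = len(block_sizes)
    starts = np.concatenate(([0], np.cumsum(block_sizes)))
    labels: List[str] = []
    active_sets: List[Tuple[int, ...]] = []
    for l in range(L):
        active = []
        for h in range(H):
            block = absmean[starts[h]:starts[h + 1], l]
            if block.mean() > tau * global_mean:
                active.append(h)
        active_sets.append(tuple(active))
        k = len(active)
        if k == 0:
            labels.append("null")
        elif k == H:
            labels.append("all_shared")
        elif k == 1:
            labels.append("specific")
        else:
            labels.append("subset_shared")
    return labels, active_sets


def predict_outcomes(
    W_hat: np.ndarray,
    m_hat: np.ndarray,
    B_hat: np.ndarray,
    beta0_hat: np.ndarray,
    test_modalities: Sequence[ModalityData],
    graph: FeatureGraph,
    hyper: Hyperparams,
    chain_config: Optional[ChainConfig] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Predict test outcomes by re-fitting the latent factors.

    The model (without its outcome component) is re-run on the test data
    with the loadings and location frozen at their training posterior
    means; only Z, the Gaussian precisions and the Pólya-Gamma variables
    are updated.  Returns (Y_hat = beta0 + B Z_hat, Z_hat).
    """
    W_hat = np.asarray(W_hat, dtype=float)
    p = sum(m.p for m in test_modalities)
    if W_hat.shape[0] != p:
        raise ValidationError(
            f"trained loadings have p={W_hat.shape[0]} but test data has p={p}"
        )
    if chain_config is None:
        chain_config = ChainConfig(n_iter=2000, n_burnin=1000, thin=2)
    samples = run_chain(
        list(test_modalities), None, graph, hyper, chain_config,
        L=W_hat.shape[1], fixed_W=W_hat, fixed_m=np.asarray(m_hat, float),
    )
    Z_hat = samples.Z.mean(axis=0)
    B_hat = np.atleast_2d(np.asarray(B_hat, dtype=float))
    beta0_hat = np.atleast_1d(np.asarray(beta0_hat, dtype=float))
    Y_hat = beta0_hat[:, None] + B_hat @ Z_hat
    return Y_hat, Z_hat
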