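"""Model/Results interface to the supervised graph-guided factor model.

``SGBFAModel`` is built from data (a list of modality blocks, optional
outcomes and an optional feature graph); ``fit`` runs the MCMC and returns
an ``SGBFAResults`` carrying posterior means, traces, diagnostics, DIC,
factor classification and test-set prediction.

Example
-------
>>> from sgbfa import simulate, SGBFAModel
>>> sim = simulate.simulate_dataset(simulate.ScenarioSpec(seed=1))
>>> model = SGBFAModel(sim.modalities, graph=sim.graph, n_factors=4)
>>> res = model.fit(n_iter=500, burnin=250, seed=1)
>>> print(res.summary())                            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import (
    ChainConfig,
    Hyperparams,
    ModalityData,
    ValidationError,
)
from .evaluate import classify_factors, mse, predict_outcomes, rre
from .graph import FeatureGraph
from .sampler import PosteriorSamples, posterior_mean_mu, run_chain
from .tuning import DicResult, compute_dic, grid_search

__all__ = ["SGBFAModel", "SGBFAResults"]


class SGBFAModel:
    """Supervised graph-guided Bayesian factor model.

    Parameters
    ----------
    modalities : sequence of ModalityData
        The omics blocks, sharing one sample dimension.
    outcomes : ndarray (p_y, n), optional
        Continuous outcomes regressed on the latent factors during fitting.
    graph : FeatureGraph, optional
        Intra-modality feature graphs guiding the shrinkage prior; the
        null graph is used when omitted.
    n_factors : int
        Number of latent factors L.
    hyper : Hyperparams, optional
        Prior hyperparameters (defaults are weakly informative with
        eta=10, epsilon=0.2 fixed).
    """

    def __init__(
        self,
        modalities: Sequence[ModalityData],
        outcomes: Optional[np.ndarray] = None,
        graph: Optional[FeatureGraph] = None,
        n_factors: int = 4,
        hyper: Optional[Hyperparams] = None,
    ):
        self.modalities = list(modalities)
        if graph is None:
            graph = FeatureGraph.empty(self.modalities)
        self.graph = graph
        self.outcomes = None if outcomes is None else \
            np.atleast_2d(np.asarray(outcomes, dtype=float))
        self.n_factors = int(n_factors)
        if self.n_factors < 1:
            raise ValidationError("n_factors must be >= 1")
        self.hyper = hyper if hyper is not None else Hyperparams()

    @classmethod
    def from_dataframes(
        cls,
        frames: Dict[str, pd.DataFrame],
        families: Dict[str, str],
        outcomes: Optional[pd.DataFrame] = None,
        trials: Optional[Dict[str, np.ndarray]] = None,
        failures: Optional[Dict[str, np.ndarray]] = None,
        graph: Optional[FeatureGraph] = None,
        n_factors: int = 4,
        hyper: Optional[Hyperparams] = None,
    ) -> "SGBFAModel":
        """Build from feature-by-sample DataFrames keyed by modality name."""
        mods = []
        for name, df in frames.items():
            mods.append(ModalityData(
                name=name, X=df.to_numpy(dtype=float),
                family=families[name],
                trials=None if trials is None else trials.get(name),
                failures=None if failures is None else failures.get(name),
                feature_ids=[str(i) for i in df.index],
            ))
        Y = None if outcomes is None else outcomes.to_numpy(dtype=float)
        return cls(mods, outcomes=Y, graph=graph, n_factors=n_factors,
                   hyper=hyper)

    def fit(
        self,
        n_iter: int = 5000,
        burnin: Optional[int] = None,
        thin: int = 5,
        seed: int = 0,
        **config_kwargs,
    ) -> "SGBFAResults":
        """Run the MCMC and return a results object."""
        if burnin is None:
            burnin = n_iter // 2
        config = ChainConfig(n_iter=n_iter, n_burnin=burnin, thin=thin,
                             seed=seed, **config_kwargs)
        samples = run_chain(
            self.modalities, self.outcomes, self.graph, self.hyper,
            config, L=self.n_factors,
        )
        return SGBFAResults(self, samples)

    def tune(
        self,
        grid: Sequence[Tuple[float, float, int]],
        n_iter: int = 2000,
        burnin: Optional[int] = None,
        thin: int = 5,
        seed: int = 0,
    ):
        """DIC grid search over (nu1, nu2, L); returns (best, table, results).

        The winning configuration is re-fit at full length and wrapped in
        an ``SGBFAResults``.
        """
        if burnin is None:
            burnin = n_iter // 2
        config = ChainConfig(n_iter=n_iter, n_burnin=burnin, thin=thin,
                             seed=seed)
        best, table, final = grid_search(
            self.modalities, self.outcomes, self.graph, self.hyper,
            grid, config, final_full_run=True,
        )
        tuned = SGBFAModel(
            self.modalities, outcomes=self.outcomes, graph=self.graph,
            n_factors=best[2],
            hyper=replace(self.hyper, nu1=best[0], nu2=best[1]),
        )
        return best, table, SGBFAResults(tuned, final)


class SGBFAResults:
    """Posterior summaries of a fitted model."""

    def __init__(self, model: SGBFAModel, samples: PosteriorSamples):
        self.model = model
        self.samples = samples
        self._mu_cache: Optional[Tuple[np.ndarray, np.ndarray]] = None

    # -- posterior means ---------------------------------------------------
    def _mu(self) -> Tuple[np.ndarray, np.ndarray]:
        if self._mu_cache is None:
            self._mu_cache = posterior_mean_mu(self.samples)
        return self._mu_cache

    @property
    def mu_hat(self) -> np.ndarray:
        """Posterior-mean modality mean structure (p x n, link scale)."""
        return self._mu()[0]

    @property
    def mu_y_hat(self) -> np.ndarray:
        """Posterior-mean outcome mean structure (p_y x n)."""
        return self._mu()[1]

    @property
    def W_hat(self) -> np.ndarray:
        return self.samples.W.mean(axis=0)

    @property
    def Z_hat(self) -> np.ndarray:
        return self.samples.Z.mean(axis=0)

    @property
    def m_hat(self) -> np.ndarray:
        return self.samples.m.mean(axis=0)

    @property
    def B_hat(self) -> np.ndarray:
        return self.samples.B.mean(axis=0)

    @property
    def beta0_hat(self) -> np.ndarray:
        return self.samples.beta0.mean(axis=0)

    @property
    def mh_acceptance_rate(self) -> float:
        return self.samples.mh_acceptance_rate

    # -- diagnostics and summaries ----------------------------------------
    def dic(self) -> DicResult:
        return compute_dic(
            self.samples, self.model.modalities, self.model.outcomes,
            nu1=self.model.hyper.nu1, nu2=self.model.hyper.nu2,
        )

    def classify_factors(self, tau: float = 0.1):
        """Factor-type labels and active modality sets from |W| draws."""
        return classify_factors(
            self.samples.W, self.samples.block_sizes, tau=tau
        )

    def reconstruction_error(self, mu_true: np.ndarray) -> float:
        """Relative reconstruction error of the omics mean structure."""
        return rre(self.mu_hat, mu_true)

    def predict(
        self,
        test_modalities: Sequence[ModalityData],
        n_iter: int = 2000,
        burnin: Optional[int] = None,
        thin: int = 2,
        seed: int = 0,
    ) -> np.ndarray:
        """Predict outcomes for new samples: refit Z with W, m frozen."""
        if self.model.outcomes is None:
            raise ValidationError("model was fitted without outcomes")
        if burnin is None:
            burnin = n_iter // 2
        config = ChainConfig(n_iter=n_iter, n_burnin=burnin, thin=thin,
                             seed=seed)
        Y_hat, _ = predict_outcomes(
            self.W_hat, self.m_hat, self.B_hat, self.beta0_hat,
            test_modalities, self.model.graph, self.model.hyper,
            chain_config=config,
        )
        return Y_hat

    def score(self, test_modalities, Y_test, **kwargs) -> np.ndarray:
        """Per-outcome test MSE."""
        return mse(np.atleast_2d(Y_test), self.predict(test_modalities,
                                                       **kwargs))

    def summary(self) -> str:
        """Plain-text fit summary."""
        names = self.samples.modality_names
        labels, active = self.classify_factors()
        lines = [
            "Supervised graph-guided Bayesian factor model",
            "=" * 54,
            f"modalities: {len(names)} ({', '.join(names)})",
            f"features p = {self.samples.W.shape[1]}, "
            f"samples n = {self.samples.Z.shape[2]}, "
            f"factors L = {self.samples.W.shape[2]}",
            f"outcomes p_y = {self.samples.B.shape[1]}",
            f"stored draws = {self.samples.n_draws}",
            f"MH acceptance (log-shrinkage) = "
            f"{self.samples.mh_acceptance_rate:.3f}",
            f"mean log-likelihood = {np.mean(self.samples.log_likelihood):.2f}",
            "-" * 54,
            "factor  type           active modalities",
        ]
        for l, (lab, act) in enumerate(zip(labels, active)):
            mods = ", ".join(names[h] for h in act) if act else "-"
            lines.append(f"{l + 1:>6}  {lab:<13}  {mods}")
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Trace plot of the stored joint log-posterior (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.samples.log_posterior)
        ax.set_xlabel("stored draw")
        ax.set_ylabel("joint log-posterior")
        return ax
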