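import numpy as np
import pytest

from sgbfa.data import Hyperparams, ModalityData
from sgbfa.graph import FeatureGraph


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def tiny_gaussian():
    """Two small Gaussian modalities with precisions set."""
    rng = np.random.default_rng(11)
    mods = [
        ModalityData(
            name="expr", X=rng.normal(size=(3, 5)), family="gaussian",
            precision=np.array([1.0, 2.0, 0.5]),
        ),
        ModalityData(
            name="metab", X=rng.normal(size=(2, 5)), family="gaussian",
            precision=np.array([1.5, 1.0]),
        ),
    ]
    return mods


@pytest.fixture
def tiny_mixed():
    """Gaussian + binomial + negative-binomial modalities, n = 4."""
    rng = np.random.default_rng(5)
    gauss = ModalityData(
        name="g", X=rng.normal(size=(2, 4)), family="gaussian",
        precision=np.array([1.0, 1.0]),
    )
    trials = np.array([1, 3])
    binom = ModalityData(
        name="b", X=np.array([[0, 1, 1, 0], [2, 0, 3, 1]], dtype=float),
        family="binomial", trials=trials,
    )
    nb = ModalityData(
        name="nb", X=np.array([[0, 2, 1, 4]], dtype=float),
        family="negative_binomial", failures=np.array([2.5]),
    )
    return [gauss, binom, nb]


@pytest.fixture
def pair_graph(tiny_gaussian):
    """Disjoint-pair graph over the tiny Gaussian fixture (one edge/blk)."""
    mods = tiny_gaussian
    return FeatureGraph(
        modality_names=[m.name for m in mods],
        feature_ids={m.name: list(m.feature_ids) for m in mods},
        edges={"expr": {(0, 1)}, "metab": {(0, 1)}},
    )


@pytest.fixture
def hyper():
    return Hyperparams()
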