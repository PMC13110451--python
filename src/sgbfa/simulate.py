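"""Synthetic multi-modal data generator.

Emulates the two benchmark designs used to validate the model: block-sparse
loading matrices in four group structures (full / ai / pi / ap), star-shaped
pathway graphs and their perturbations G0-G4, Gaussian / binary / binomial /
mixed modality types, and optional continuous outcomes regressed on the
latent factors.

Fixed generative conventions:

* nonzero loadings and all latent factors are N(0, 1.5^2);
* the location vector m is 0;
* Gaussian observation noise is N(0, sigma^2) with sigma = 1 by default;
* binomial trial counts are drawn uniformly from {1,...,10} per feature
  (identically 1 for binary modalities);
* outcome coefficients are U(1, 2), the intercept is 0, and outcome noise
  variance sigma_y^2 is one of {1, 2, 3} (low / medium / high).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .data import ModalityData, ValidationError
from .graph import FeatureGraph, _norm_edge

__all__ = [
    "ScenarioSpec",
    "SimulatedDataset",
    "make_star_pathways",
    "perturb_graph",
    "make_loading_structure",
    "simulate_dataset",
]

STRUCTURES = ("full", "ai", "pi", "ap")
GRAPH_VARIANTS = ("G0", "G1", "G2", "G3", "G4")
DATA_TYPES = ("gaussian", "binary", "binomial", "mixed")
LOADING_SD = 1.5


@dataclass
class ScenarioSpec:
    """Configuration of one simulated scenario."""

    structure: str = "ai"
    data_type: str = "gaussian"
    H: int = 5
    p_per_modality: int = 100
    n: int = 200
    n_train: Optional[int] = None  # None -> no split (all training)
    n_pathways: int = 10
    gaussian_noise_sd: float = 1.0
    n_outcomes: int = 0
    outcome_noise_var: float = 1.0
    graph_variant: str = "G2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValidationError(f"unknown structure {self.structure!r}")
        if self.data_type not in DATA_TYPES:
            raise ValidationError(f"unknown data type {self.data_type!r}")
        if self.graph_variant not in GRAPH_VARIANTS:
            raise ValidationError(f"unknown graph variant {self.graph_variant!r}")
        if self.data_type == "mixed" and self.H != 5:
            raise ValidationError("mixed data type requires H = 5")
        if self.p_per_modality % self.n_pathways:
            raise ValidationError(
                "p_per_modality must be divisible by n_pathways"
            )
        if self.n_train is not None and not (0 < self.n_train < self.n):
            raise ValidationError("need 0 < n_train < n")

    @property
    def L(self) -> int:
        return 10 if self.structure == "full" else 4

    @property
    def families(self) -> List[str]:
        if self.data_type == "gaussian":
            return ["gaussian"] * self.H
        if self.data_type == "binary":
            return ["binary"] * self.H
        if self.data_type == "binomial":
            return ["binomial"] * self.H
        return ["gaussian", "gaussian", "binomial", "binomial", "binary"]


@dataclass
class SimulatedDataset:
    """Ground truth plus observed data of one scenario."""

    spec: ScenarioSpec
    modalities: List[ModalityData]
    Y: Optional[np.ndarray]
    graph: FeatureGraph
    W: np.ndarray
    Z: np.ndarray
    m: np.ndarray
    B: Optional[np.ndarray]
    mu: np.ndarray
    mask: np.ndarray  # boolean (p, L) loading support

    def split(self) -> Tuple["SimulatedDataset", "SimulatedDataset"]:
        """Train/test split along samples (first n_train columns train)."""
        nt = self.spec.n_train
        if nt is None:
            raise ValidationError("scenario has no train/test split")
        return self._take(slice(0, nt)), self._take(slice(nt, self.spec.n))

    def _take(self, cols: slice) -> "SimulatedDataset":
        import copy
        mods = [
            ModalityData(
                name=m.name, X=m.X[:, cols], family=m.family,
                trials=None if m.trials is None else m.trials.copy(),
                failures=None if m.failures is None else m.failures.copy(),
                feature_ids=list(m.feature_ids),
            )
            for m in self.modalities
        ]
        return SimulatedDataset(
            spec=self.spec, modalities=mods,
            Y=None if self.Y is None else self.Y[:, cols],
            graph=self.graph, W=self.W, Z=self.Z[:, cols], m=self.m,
            B=self.B, mu=self.mu[:, cols], mask=self.mask,
        )


def make_star_pathways(p_h: int, n_pathways: int) -> set:
    """Star-pathway edge set for one modality.

    Pathway i spans features (p_h/n_pathways)*(i-1) ... (p_h/n_pathways)*i
    (0-based, contiguous); the first feature of each pathway is the hub and
    is connected to every other member, with no member-member edges.
    """
    if p_h % n_pathways:
        raise ValidationError("p_h must be divisible by n_pathways")
    size = p_h // n_pathways
    edges = set()
    for i in range(n_pathways):
        center = i * size
        for member in range(center + 1, center + size):
            edges.add((center, member))
    return edges


def _pathway_of(j: int, size: int) -> int:
    return j // size


def perturb_graph(g2: FeatureGraph, variant: str,
                  rng: np.random.Generator,
                  pathway_size: int) -> FeatureGraph:
    """Derive a working graph from the true star graph G2.

    G0: no edges.  G1: each G2 edge kept with probability 0.7.
    G3: G2 plus each absent within-pathway pair added with probability 0.3.
    G4: G3 plus each absent across-pathway pair added with probability 0.1.
    """
    if variant not in GRAPH_VARIANTS:
        raise ValidationError(f"unknown graph variant {variant!r}")
    out = FeatureGraph(
        modality_names=list(g2.modality_names),
        feature_ids={k: list(v) for k, v in g2.feature_ids.items()},
        edges={k: set() for k in g2.modality_names},
    )
    if variant == "G0":
        return out
    if variant == "G2":
        out.edges = {k: set(v) for k, v in g2.edges.items()}
        return out
    for name in g2.modality_names:
        p_h = len(g2.feature_ids[name])
        base = set(g2.edges[name])
        if variant == "G1":
            kept = {e for e in sorted(base) if rng.random() >= 0.3}
            out.edges[name] = kept
            continue
        edges = set(base)
        # G3: densify pathways
        for i, j in itertools.combinations(range(p_h), 2):
            if _pathway_of(i, pathway_size) != _pathway_of(j, pathway_size):
                continue
            e = _norm_edge(i, j)
            if e not in edges and rng.random() < 0.3:
                edges.add(e)
        if variant == "G4":
            for i, j in itertools.combinations(range(p_h), 2):
                if _pathway_of(i, pathway_size) == _pathway_of(j, pathway_size):
                    continue
                e = _norm_edge(i, j)
                if e not in edges and rng.random() < 0.1:
                    edges.add(e)
        out.edges[name] = edges
    return out


def _factor_modality_pattern(structure: str, H: int) -> List[List[int]]:
    """Which modalities load on each factor, per group structure.

    full (L=10): 2 all-shared, then subset-shared pairs of breadth H-1,
    H-2, 2, then 2 modality-specific; ai (L=4): 2 all-shared + 2 specific;
    pi: 2 subset-shared + 2 specific; ap: 2 all-shared + 2 subset-shared.
    Subsets are contiguous modality runs; specific factors go to the first
    modalities in turn.
    """
    all_mods = list(range(H))

    def contiguous(start: int, size: int) -> List[int]:
        return [(start + k) % H for k in range(size)]

    if structure == "full":
        sizes = [H, H, max(H - 1, 2), max(H - 1, 2), max(H - 2, 2),
                 max(H - 2, 2), 2, 2, 1, 1] if H > 1 else [1] * 10
        pattern = []
        for idx, size in enumerate(sizes):
            size = min(size, H)
            pattern.append(contiguous(idx % H, size) if size < H else all_mods)
        return pattern
    if structure == "ai":
        return [all_mods, all_mods, [0], [1 % H]]
    if structure == "pi":
        sub = max(2, min(H - 1, (H + 1) // 2 + 1)) if H > 2 else H
        return [contiguous(0, sub), contiguous(H // 2, sub), [0], [1 % H]]
    # ap
    sub = max(2, min(H - 1, (H + 1) // 2 + 1)) if H > 2 else H
    return [all_mods, all_mods, contiguous(0, sub), contiguous(H // 2, sub)]


def make_loading_structure(structure: str, H: int,
                           p_h_list: Sequence[int],
                           pathway_size: int = 10) -> np.ndarray:
    """Boolean support mask (p x L) of the block-sparse loading matrix.

    Each factor is active on a named set of modalities; within an active
    modality block the nonzero rows cover alternating whole pathways
    (factor l takes pathways with index parity l mod 2), so half the rows
    are nonzero and the star graph is informative about the support: all
    active features of a pathway share a factor.
    """
    if structure not in STRUCTURES:
        raise ValidationError(f"unknown structure {structure!r}")
    pattern = _factor_modality_pattern(structure, H)
    L = len(pattern)
    starts = np.concatenate(([0], np.cumsum(p_h_list)))
    p = int(starts[-1])
    mask = np.zeros((p, L), dtype=bool)
    for l, mods in enumerate(pattern):
        for h in mods:
            p_h = p_h_list[h]
            rows = np.arange(p_h)
            take = (rows // pathway_size) % 2 == (l % 2)
            mask[starts[h] + rows[take], l] = True
    return mask


def simulate_dataset(spec: ScenarioSpec) -> SimulatedDataset:
    """Generate one full scenario (data, outcomes, graph, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    H, n, L = spec.H, spec.n, spec.L
    p_h_list = [spec.p_per_modality] * H
    pathway_size = spec.p_per_modality // spec.n_pathways
    mask = make_loading_structure(spec.structure, H, p_h_list, pathway_size)
    p = mask.shape[0]
    W = np.where(mask, rng.normal(0.0, LOADING_SD, size=(p, L)), 0.0)
    Z = rng.normal(0.0, LOADING_SD, size=(L, n))
    m = np.zeros(p)
    mu = m[:, None] + W @ Z

    names = [f"mod{h + 1}" for h in range(H)]
    families = spec.families
    modalities: List[ModalityData] = []
    start = 0
    for h, (name, fam) in enumerate(zip(names, families)):
        p_h = p_h_list[h]
        mu_h = mu[start:start + p_h]
        if fam == "gaussian":
            X = mu_h + rng.normal(0.0, spec.gaussian_noise_sd, size=mu_h.shape)
            modalities.append(ModalityData(name=name, X=X, family="gaussian"))
        else:
            if fam == "binary":
                trials = np.ones(p_h, dtype=int)
            else:
                trials = rng.integers(1, 11, size=p_h)
            prob = 1.0 / (1.0 + np.exp(-mu_h))
            X = rng.binomial(trials[:, None], prob).astype(float)
            modalities.append(
                ModalityData(name=name, X=X, family="binomial", trials=trials)
            )
        start += p_h

    star = {
        name: make_star_pathways(spec.p_per_modality, spec.n_pathways)
        for name in names
    }
    g2 = FeatureGraph(
        modality_names=names,
        feature_ids={m.name: list(m.feature_ids) for m in modalities},
        edges=star,
    )
    graph = perturb_graph(g2, spec.graph_variant, rng, pathway_size)

    if spec.n_outcomes > 0:
        B = rng.uniform(1.0, 2.0, size=(spec.n_outcomes, L))
        noise = rng.normal(0.0, np.sqrt(spec.outcome_noise_var),
                           size=(spec.n_outcomes, n))
        Y = B @ Z + noise  # zero intercept
    else:
        B, Y = None, None

    return SimulatedDataset(
        spec=spec, modalities=modalities, Y=Y, graph=graph,
        W=W, Z=Z, m=m, B=B, mu=mu, mask=mask,
    )
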