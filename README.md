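# sgbfa — supervised graph-guided Bayesian factor analysis

`sgbfa` learns a sparse low-dimensional representation of multi-modal
omics data (transcriptomics, proteomics, metabolomics, genotype dosages,
…) **jointly** with a regression of one or more continuous clinical
outcomes on the latent factors.  It is aimed at integrative analyses
where n ≪ p, where modalities share some biology but not all of it, and
where pathway/interaction graphs are available and worth exploiting.

## Model

Each modality block X⁽ʰ⁾ (p_h features × n samples; Gaussian, binomial,
or negative-binomial with a logit link) is tied to shared latent factors
through

    μ⁽ʰ⁾ = m⁽ʰ⁾ 1ᵀ + W⁽ʰ⁾ Z ,         y_j = β_j0 + Zᵀ β_j + ε_j ,

with two-level adaptive shrinkage on the loadings,

    w_jl⁽ʰ⁾ ~ Laplace(rate = φ_l⁽ʰ⁾ λ_jl⁽ʰ⁾),

where the modality-level rates φ switch whole blocks of a factor off
(classifying factors as shared by all, a subset, or one modality) and the
feature-level rates λ select features.  Biological graphs enter through
the prior on 𝒜 = log Λ: its columns are Gaussian with precision
proportional to Ω, and Ω has a graph-constrained Wishart prior

    log π(Ω) = C + (η(1+ε)/2) log|Ω| − (η/2) tr((11ᵀ + εI) Ω),  Ω ∈ ℳ_𝒢 ,

so connected features get correlated shrinkage and are co-selected, with
ε controlling the coupling smoothly (η = 10, ε = 0.2 fixed).  Inference
is by MCMC (Pólya-Gamma and normal-exponential augmentation, adaptive
Metropolis for 𝒜, exact/clique-Gibbs G-Wishart draws for Ω); the number
of factors L and (ν₁, ν₂) are chosen by a DIC grid search.  See
`docs/methods.md` for the full specification.

## Worked example

```python
import numpy as np
from sgbfa import ScenarioSpec, SGBFAModel, simulate_dataset
from sgbfa.evaluate import mse

spec = ScenarioSpec(structure="ai", data_type="gaussian", H=5,
                    p_per_modality=40, n=200, n_train=150, n_pathways=4,
                    n_outcomes=1, outcome_noise_var=1.0,
                    graph_variant="G2", seed=7)
sim = simulate_dataset(spec)
train, test = sim.split()

model = SGBFAModel(train.modalities, outcomes=train.Y,
                   graph=train.graph, n_factors=4)
result = model.fit(n_iter=800, burnin=400, thin=4, seed=7)
print(result.summary())
print(f"train RRE = {result.reconstruction_error(train.mu):.3f}")
y_hat = result.predict(test.modalities, n_iter=400, seed=7)
print(f"test MSE  = {mse(test.Y, y_hat)[0]:.3f}")
```

Output:

```
Supervised graph-guided Bayesian factor model
======================================================
modalities: 5 (mod1, mod2, mod3, mod4, mod5)
features p = 200, samples n = 150, factors L = 4
outcomes p_y = 1
stored draws = 100
MH acceptance (log-shrinkage) = 0.339
mean log-likelihood = -42512.43
------------------------------------------------------
factor  type           active modalities
     1  all_shared     mod1, mod2, mod3, mod4, mod5
     2  all_shared     mod1, mod2, mod3, mod4, mod5
     3  specific       mod2
     4  specific       mod1
train RRE = 0.086
test MSE  = 1.211
```

The generator planted two factors shared by all five modalities and two
modality-specific ones (`structure="ai"`); the fit recovers exactly that
typology.  RRE is the relative Frobenius error of the reconstructed mean
structure (0 = perfect, 1 = the trivial zero estimate), so 0.086 means
the low-rank structure is essentially recovered.  The test MSE of 1.211
sits just above the irreducible outcome-noise variance of 1.0: the
regression layer predicts held-out outcomes near the oracle floor.

## Command line

A thin CLI wraps the same objects:

```sh
sgbfa simulate --structure ai --outcomes 1 --train 200 --seed 1 --out data/
sgbfa fit data/ --factors 4 --iters 2000 --out archive/
sgbfa tune data/ --iters 1000 --out tuned/
sgbfa predict archive/ testdata/ --out pred.tsv
sgbfa evaluate --truth data/truth --mu-hat archive/Z_hat.tsv --out report.json
sgbfa repro-sim1 --graphs G0,G2 --reps 3 --out sim1/
sgbfa repro-sim2 --outcomes 1 --noise low --reps 3 --out sim2/
```

Bundles are plain TSV matrices plus a JSON manifest; graphs are
two-column edge lists of feature IDs.

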