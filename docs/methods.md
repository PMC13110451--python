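# Methods

## Model

`sgbfa` fits a supervised, graph-guided Bayesian factor model to a
collection of H omics blocks ("modalities") X⁽¹⁾, …, X⁽ᴴ⁾ measured on the
same n samples, optionally together with p_y continuous outcomes Y.  Each
block has a likelihood family — Gaussian, binomial, or negative binomial —
and a block-specific linear predictor

    μ⁽ʰ⁾ = m⁽ʰ⁾ 1ᵀ + W⁽ʰ⁾ Z ,

where Z (L × n) are latent factors shared by all blocks, W⁽ʰ⁾ (p_h × L)
are loadings and m⁽ʰ⁾ is a per-feature location.  For Gaussian features μ
is the mean (with per-feature precision ρ_j); for binomial and
negative-binomial features μ is the log-odds of the success probability
(trial counts n_j and failure parameters r_j are fixed per feature; binary
data is binomial with n_j = 1, and {0,1,2} genotype dosages are binomial
with n_j = 2).  Outcomes are Gaussian regressions on the factors:
y_j = β_j0 + Zᵀβ_j + ε_j, ε_j ~ N(0, 1/ρ_yj).  Fitting the factor and
regression layers jointly lets the outcome inform the representation.

## Priors and the graph layer

Loadings and outcome coefficients carry Laplace priors with two-level
adaptive rates:

    w_jl⁽ʰ⁾ ~ Laplace(rate = φ_l⁽ʰ⁾ λ_jl⁽ʰ⁾),   β_jl ~ Laplace(rate = λ_jlʸ),

where φ_l⁽ʰ⁾ (gamma prior, shape a_φ, rate b_φ) shrinks whole
modality-blocks of a factor (giving block sparsity and the factor
typology: all-shared / subset-shared / modality-specific / null) and
λ_jl⁽ʰ⁾ shrinks individual features.  The logs of the feature-level rates,
𝒜 = log Λ, are coupled through the biological graph: columns of 𝒜 are
Gaussian with mean ν₁1 and covariance ν₂ Ω⁻¹, and Ω carries a constrained
Wishart prior

    log π(Ω) = C + (η(1+ε)/2) log|Ω| − (η/2) tr((11ᵀ + εI) Ω),

restricted to symmetric PD matrices whose off-diagonal support lies in the
(intra-modality) edge set.  The unconstrained mode of this prior is the
inverse of (11ᵀ + εI)/(1+ε), so Ω⁻¹ off-diagonals concentrate near
1/(1+ε): ε controls the shrinkage-coupling strength smoothly (avoiding the
phase-transition behaviour of Markov-random-field alternatives) and η the
prior weight.  η = 10, ε = 0.2 are fixed throughout.  Remaining priors:
z_li ~ N(0,1); m and β₀ Gaussian with variances σ_m², σ_b²; outcome and
Gaussian-feature precisions Gamma(ζ/2, ζ/2).

Normalizing constants are included in every stored prior log-density
except the graph-constrained Wishart, whose constant under the support
restriction is intractable; only differences of that term are ever used
(Metropolis ratios), and the DIC uses likelihoods only, so this is safe.

The Gaussian feature-precision prior is the package's own choice:
Gamma(ζ/2, ζ/2), adopted by symmetry with the outcome precision prior
(ζ = 1 by default).

## Posterior computation

All conditionals are made tractable by exact data augmentation:

* **Laplace → normal-exponential mixture.**  Each Laplace coefficient is a
  scale mixture w ~ N(0, s), s ~ Exp(rate²/2); 1/s has an inverse-Gaussian
  full conditional.  Rows of W and of (β₀, B) then have Gaussian full
  conditionals solved in batched L×L (or (L+1)×(L+1)) systems.
* **Logit likelihoods → Pólya-Gamma.**  Binomial and negative-binomial
  cells receive ω ~ PG(b, μ) with b = n_j or r_j + x; the likelihood
  becomes a Gaussian pseudo-likelihood with working precision ω and
  working observation κ/ω, κ = x − b/2 (binomial) or (x − r)/2 (NB).
  The PG sampler is implemented in-package: exact Devroye rejection for
  integer shapes ≤ 30, truncated infinite-gamma-convolution (200 terms,
  mean-matched remainder) otherwise.
* **Shrinkage layers.**  φ and λʸ are updated from collapsed conjugate
  gamma conditionals given (W, B) with the mixture scales integrated out;
  the scales are redrawn from their exact conditional at the top of each
  sweep before anything conditions on them again, which makes the sweep a
  valid partially collapsed Gibbs sampler.
* **𝒜 (log feature rates).**  Per-entry Gaussian random-walk Metropolis.
  Entries in different columns, or in the same graph-coloring class of the
  feature graph, have no direct coupling through Ω and are proposed and
  accepted in parallel (greedy coloring per modality).  Step sizes adapt
  multiplicatively toward 0.3 acceptance during burn-in only, every 25
  sweeps, and are frozen afterwards so the stationary law is untouched.
* **Ω (G-Wishart full conditional).**  Given 𝒜, Ω | 𝒜 is a constrained
  Wishart with δ′ = η(1+ε) + L + 2 and rate D′ = η(11ᵀ+εI) +
  (1/ν₂)Σ_l α̃_l α̃_lᵀ, restricted to the graph and block-diagonal over
  modalities.  Sampling is per connected component: isolated nodes are
  exact gamma draws; complete components are exact Wishart draws
  (Bartlett); star components (the simulation's pathway unit) use an exact
  closed-form factorization — the hub's Schur complement is gamma, leaf
  diagonals are gammas, hub–leaf entries are conditionally normal — fully
  vectorized across stars; any other component uses a block-Gibbs scan
  over maximal cliques (the clique block minus its Schur complement
  against the rest is Wishart), warm-started from the current value,
  which leaves the conditional invariant inside the outer Gibbs sweep.

Sweep order: augmentation → W → Z → (m, ρ) → (β₀, B, ρ_y) → (Φ, Λʸ) →
𝒜 (MH) → Ω.  Chains are fully reproducible given the seed.  The joint
log-posterior is checked for finiteness every 100 sweeps; a NaN aborts
with a diagnostic.  The chain starts from an SVD of the link-scale,
location-centred data (loadings/factors), ridge fits (regression), Φ = 1,
𝒜 = ν₁, Ω = I; this start shortens burn-in substantially and is why the
shortened chains below mix adequately.

Rotation and sign of (W, Z) are not identified and are left unresolved;
every reported summary (μ̂, μ̂_y, DIC, RRE, MSE) is rotation-invariant, and
factor typing uses per-draw |W| averages.

## Model selection

DIC variant over the full data log-likelihood (omics blocks plus
outcomes):  DIC = −2 l(D, Û) + 4(l(D, Û) − mean_t l(D, U_t)), with Û the
posterior-mean structure (μ̂, μ̂_y).  Evaluating l at Û requires
precisions; posterior means of ρ and ρ_y are used there.  Binomial
log-choose constants are kept in stored likelihoods so DIC is comparable
across L.  `grid_search` fits one half-length chain per (ν₁, ν₂, L) grid
point (default grid ν₁ ∈ {−2,0,2}, ν₂ ∈ {0.5,1,2}, L ∈ {2,4,6,8,10,12,16})
and breaks exact ties toward smaller L, then ν₂, then ν₁; failed points
are excluded with a warning.

## Held-out prediction

Test outcomes are predicted by re-running the sampler on the test block
data with W and m frozen at their training posterior means and the outcome
layer removed: only Z, the Gaussian precisions and the Pólya-Gamma
variables update.  Predictions are β̂₀ + B̂ Ẑ with Ẑ the posterior-mean
factors of that reduced chain.

## Synthetic-data generator

`simulate` reproduces the benchmark designs: H = 5 modalities of 100
features each by default; four block-sparsity structures for W — `full`
(L = 10; activity breadth per factor 5,5,4,4,3,3,2,2,1,1 over modalities),
`ai` (L = 4; two all-shared + two specific), `pi` (two subset-shared + two
specific), `ap` (two all-shared + two subset-shared).  Nonzero loadings
and all factor scores are N(0, 1.5²); m = 0.  Gaussian blocks add
N(0, σ²) noise; the default σ = 1 puts unit-variance noise against
1.5-sd signal, a moderate-noise regime.  Binomial trials are uniform on {1,…,10} (≡ 1 for binary
modalities); the mixed design is (gaussian, gaussian, binomial, binomial,
binary).  Outcomes use β_j ~ U(1,2), zero intercept, noise variance
σ_y² ∈ {1, 2, 3} mapped to low/medium/high.

Each modality carries 10 equal star pathways (hub = first feature of each
pathway).  Working graphs: G0 empty; G2 the true stars; G1 deletes G2
edges w.p. 0.3; G3 adds absent within-pathway pairs w.p. 0.3; G4 further
adds across-pathway pairs w.p. 0.1.

Within an active modality-block a factor loads on alternating whole
pathways (factor parity), giving 50% nonzero rows.  Whole pathways — not
half-pathway runs — are used so that any two active features of a pathway
share a factor, keeping the star graph truthful about co-selection; this
is the one deliberate departure from a finer 5-feature block layout,
which cannot satisfy that consistency when pathways have 10 features.

What the generator does **not** emulate: real-platform feature scales and
library-size effects, missing data, inter-modality graph edges,
negative-binomial blocks (the likelihood is supported but the benchmark
designs never use it), and correlated/structured outcome noise.  Passing
the simulation checks therefore demonstrates correctness of the
algorithmic machinery under the stated generative assumptions, not
robustness to real-data artefacts.

## Evaluation

RRE = ‖μ̂ − μ‖_F / ‖μ‖_F on the omics blocks; per-outcome test MSE;
factor typing declares block (h, l) active when mean_j E|w_jl⁽ʰ⁾| exceeds
τ × the global per-entry mean |w| (τ = 0.1; the thresholding rule is an
implementation choice, exposed as a parameter).

## Replication protocol and problem sizes

The package's scaled replication of the supervised benchmark keeps the
benchmark data scale (H = 5, p = 500, 200 train / 200 test, graph G2,
L = 4) and shortens the chains — 1,000 sweeps (500 burn-in, thin 5) for
training and 600 for prediction in `scripts/acceptance.py`; 800/500 in
the test suite — and 3–5 seeds instead of 50 repeated samplings.  The
SVD start makes these lengths sufficient: trace diagnostics flatten
within ~100 sweeps on these data.  The graph-ordering and
structure-recovery checks run at p = 200 (40 features per modality, 4
pathways) with n = 100–150.  The joint-distribution (Geweke-style)
correctness check runs at p = 8, L = 2, n = 6 with one Gaussian and one
binary modality on a disjoint-pair graph (so every Ω draw is exact), with
hyperparameters a_φ = b_φ = a_λ = b_λ = ζ = 6, ν₂ = 0.5, σ_m² = σ_b² = 1
chosen so the compared prior moments have finite variance — raw moments
of w do not exist under the heavy-tailed log-normal-rate hierarchy, so
bounded tanh transforms stand in for the w moments.

## Numerical choices and edge cases

* Graph compatibility uses support ⊆ edges (tolerance 1e-12) plus a
  Cholesky PD check; an exact "iff" would fail on measure-zero draws.
* |w| is floored at 1e-10 inside inverse-Gaussian means (the w = 0 case).
* Batched Gaussian draws solve via stacked Cholesky factors.
* The G-Wishart clique scan refreshes Σ = K⁻¹ by Woodbury after each
  clique and exactly once per sweep to kill drift.
* Degenerate inputs (empty modality list, mismatched sample counts,
  missing values, non-integer binomial entries, inter-modality edges,
  non-PD Ω) raise `ValidationError` at construction.

## Known limitations

Missing data are rejected rather than imputed; inter-modality edges are
unsupported by design; the exact G-Wishart draw is one-shot only for
single-clique and star components (other components rely on a short inner
scan, exchanging per-sweep exactness for a valid warm-started kernel);
multinomial categorical features beyond the {0,1,2}-dosage recoding are
out of scope; and no EM/variational fast path exists — MCMC is the only
inference engine.
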