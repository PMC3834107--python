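# Methods

## Model

`ordercause` fits causal Gaussian Bayesian networks (GBNs) over `p` genes.
Each gene is a linear function of its parents plus an independent Gaussian
residual:

    X_j = m_j + Σ_{i ∈ pa(j)} w_ij X_i + ε_j,   ε_j ~ N(0, σ_j²),

with the parent relation acyclic. In matrix form `X = m + XW + ε`; under
any parental ordering `W` is strictly upper triangular, hence nilpotent,
and `X = mL + εL` with `L = (I − W)⁻¹ = I + W + … + W^{p−1}`. The joint
law is exactly multivariate normal, `X ~ N(mL, Lᵀ diag(σ²) L)`
(`gbn.observational_law`). Entry `(i, j)` of `L` is the total causal
effect of gene i on gene j — the derivative of `E[X_j | do(X_i = x)]` in x
— and is zero precisely when i is not an ancestor of j; `W` holds the
direct effects.

A hard intervention do(X_J = x_J) is modelled structurally: all edges
*into* the clamped set J are severed (`W_J`), the clamped coordinates are
made deterministic at their clamp values, and the remaining genes stay
Gaussian with mean `ν_J L_J` and covariance
`Σ_{j∉J} σ_j² L_Jᵀ e_jᵀ e_j L_J` (`gbn.intervention_law`). In a
linear-Gaussian structural model this clamping construction coincides
exactly with the adjustment-integral form of the intervention
distribution, so no numerical integration is needed. The clamp value
defaults to 0 — the knock-out convention — but arbitrary values
(knock-downs, over-expression) are accepted per intervention.

Feedback loops cannot be represented: acyclicity is a model assumption,
checked at construction.

## Likelihood and its closed-form profile maximum

For data `x^k` with per-sample intervention sets `J_k`, let
`K_j = {k : j ∉ J_k}` and `N_j = |K_j|`. The log-likelihood is

    ℓ(m, σ, W) = −(log 2π / 2) Σ_j N_j − Σ_j N_j log σ_j
                 − ½ Σ_k Σ_{j ∉ J_k} (x_j^k − x^k W e_jᵀ − m_j)² / σ_j².

Clamped residual terms are excluded; the residual of a *non-clamped* gene
keeps the same form in intervention samples because `W_J e_jᵀ = W e_jᵀ`
for `j ∉ J` (only incoming edges of clamped genes are severed). Given a
causal ordering, the maximiser over (m, σ, W) is available analytically
(`likelihood.ProfileLikelihood`):

1. **Weights.** For each gene j, regress column j on the genes preceding j
   in the ordering, over the rows `K_j`, after centring every column by
   its `K_j`-mean (one distinct centring per target gene). The candidate
   parent set is *all* predecessors — the complete DAG consistent with the
   ordering — since no structure prior is assumed; sparsity is judged
   downstream from effect magnitudes.
2. **Means.** `m̂_j = mean_{K_j}(x_j − x W e_jᵀ)`.
3. **Variances.** `σ̂_j² = (1/N_j) · RSS_j`, the mean squared residual.

This profile likelihood is the Metropolis–Hastings target density π over
orderings ("maximised", not marginal: a fully Bayesian treatment of θ is
out of scope).

Numerical choices:

- The per-gene normal equations are solved from the precomputed
  `K_j`-centred Gram matrix. The fast path used inside the MCMC loop
  obtains every gene's residual sum of squares from a single batched
  Cholesky factorisation of the ordering-permuted Grams (RSS of gene j =
  squared pivot at its ordering position); the per-gene path recomputes
  σ̂ from explicit residuals. Both agree to ~1e−13 and the fast path
  falls back to the exact per-gene solver whenever any relevant pivot
  drops below `sqrt(1e−10)` of the Gram scale.
- Rank-deficient systems (e.g. duplicated parent columns, or designs that
  give no information on a coefficient) are solved by minimum-norm least
  squares with relative rank tolerance 1e−10; the coefficients lying in
  the null space are reported as `degenerate_edges`, never fatal.
- σ̂ is floored at 1e−8 so noiseless fixtures keep a finite likelihood.
- A gene clamped in every sample (`N_j = 0`) contributes nothing to the
  likelihood; its `m̂_j, σ̂_j` are NaN and listed in `undefined_genes`,
  while its *outgoing* effects remain estimable through other genes'
  regressions.
- `(I − W)⁻¹` is computed by a unit-triangular solve after permuting to a
  topological order; the truncated Neumann series is kept as an
  independent cross-check (they agree to 1e−10 in the test suite).

With purely observational data the profile likelihood is **invariant to
the ordering** (any ordering's complete-DAG fit is a reparameterisation of
the same multivariate Gaussian MLE). This is the identifiability negative
result that motivates interventions, and it is enforced by tests to 1e−8.

## Mallows proposals over orderings

Proposals come from the Mallows model
`P(O* | O, φ) = φ^{d(O*, O)} / Z(φ, p)` with Kendall-tau distance d and
normaliser `Z = Π_{i=1..p} (1 + φ + … + φ^{i−1})`. The dispersion is
parameterised by a temperature, `φ = exp(−1/η)`, η > 0. Under the
formula, φ = 1 (η → ∞) is the uniform distribution over permutations and
φ → 0 (η → 0) a point mass at the reference — note this is the opposite
orientation to a description that pairs φ → 0 with uniformity; the
implementation follows the formula, which is also what makes a huge
temperature (η ~ 1e10) the "naive uniform proposal" baseline.

Sampling is exact via the repeated insertion model: the item at reference
rank i is inserted j − 1 slots before the end of the partial sequence with
probability `φ^{j−1} / (1 + φ + … + φ^{i−1})`, independently across i;
the insertion offsets sum to the Kendall distance of the result. The
density is symmetric in (O*, O), so the proposal terms cancel in the MH
ratio and the acceptance probability is `min(exp(ℓ* − ℓ), 1)`.

Only the Kendall distance is implemented; Cayley/Spearman variants and
position-specific dispersions are out of scope.

## The MCMC run

`mcmc.run_chain` starts from a uniformly random ordering, runs `n_iter`
MH steps, discards a burn-in, and keeps every `thin`-th state. Defaults
follow the benchmark schedule: 50,000 iterations, burn-in 5,000, thinning
50 (900 kept orderings); the scaled-down benchmark in this repository uses
20,000 / 2,000 / 50 (360 kept). Profile fits are memoised by ordering (a
pure-performance cache), and reported quantities are:

- the acceptance rate over post-burn-in steps;
- the node-by-position frequency matrix of the kept orderings (rows sum
  to 1) — the posterior picture of where each gene sits in the causal
  order;
- the best-likelihood fit over every ordering evaluated;
- entrywise means over the kept orderings' fitted `L` and `W` (both of
  the signed matrices and of their magnitudes).

**Temperature tuning** (`tune_eta`): for each η in 0.2, 0.3, …, 1.5 a
1,000-iteration trial run from a fresh random ordering records the
acceptance rate; the η closest to the 30–40% band wins, ties breaking
towards the smaller (sharper) η. The benchmark driver tunes once per
design on the first replicate and shares the value across replicates. On
the shipped fixture at σ = 0.1 this selects η ≈ 0.6–0.7 (and ~1 at
σ = 0.5), with acceptance rates near 0.3. The selection is flat near the
optimum: neighbouring η values often tie in practice, so the tuned value
varies with the weight draw.

**Modes.** `mallows` is the default. For purely observational data the
likelihood cannot rank orderings, so the model switches to `uniform`:
orderings drawn uniformly at random (every proposal is accepted, by
invariance), which is the correct baseline in that regime. A uniform
proposal on strongly informative knock-out data is almost always rejected
(acceptance < a few percent) — the motivation for the Mallows proposal.

**Effect estimators.** Two are provided:

- `posterior_mean` (default): detection ranking by the entrywise mean of
  |L| and |W| over the kept orderings' fits; error and correlation
  criteria on the signed entrywise means. Chosen as default because on
  observational data a "best-likelihood" ordering is arbitrary (all
  orderings tie), and because averaging shrinks the spurious complete-DAG
  coefficients that a single ordering's fit carries.
- `best`: the effect matrices of the single best-likelihood fit — the
  interpretable point estimate, also exposed as `Results.params` /
  `Results.ordering`.

## Synthetic benchmark

The generator reproduces the benchmark study conditions:

- **Network**: 10 genes, 21 edges. The true benchmark graph is published
  only as a figure, so the shipped file
  `src/ordercause/data/benchmark_dag_synthetic.tsv` is a **synthetic
  reconstruction** built to the documented structural constraints: N6 is a
  root with exactly seven descendants (admissible ordering positions 1–3),
  N3 a sink with all nine other genes as ancestors (position 10 only), and
  the partial-knock-out genes {N1, N4, N6, N7, N9} sit upstream. Every
  benchmark entry point accepts a user-supplied DAG, so results are
  reproducible relative to the shipped fixture; numbers that depend on
  fine topology (notably the observational-only AUROC) should be expected
  to differ somewhat from results on the original graph.
- **Parameters**: residual means all 0.5; residual SDs σ ∈ {0.01, 0.1,
  0.5} (small / moderate / large noise); edge weights drawn uniformly
  from (−1, −0.25) ∪ (0.25, 1) — magnitudes bounded away from zero, fair
  random sign — freshly per dataset.
- **Designs**: observational (20 wild-types); mixed (10 wild-types + one
  KO per gene); partial KO (15 wild-types + KOs of N1, N4, N6, N7, N9);
  multiple KO (mixed + five double KOs {N1,N5}, {N1,N6}, {N4,N7},
  {N6,N9}, {N7,N10}); multiple KO with three hidden genes (chosen by
  seed, recorded in the manifest). Hidden genes are removed
  post-simulation; a knock-out of a hidden gene is kept as an apparently
  observational sample by default (the intervention happened but is
  unobserved) — a switch drops such samples instead. Hidden-gene scoring
  compares against the true `L` and `W` restricted to observed×observed
  pairs, which remain well defined through hidden paths.
- **Scale**: the benchmark driver runs replicate datasets with seeds
  `seed+0 … seed+n−1`. This repository's acceptance checks use 20
  datasets per design and 20,000-iteration chains, a deliberate
  scaled-down choice that keeps the full four-design benchmark near three
  minutes on one CPU while staying within about one across-dataset SD of
  the full-scale results.

What the simulator does *not* emulate: nonlinear or dynamical (ODE)
regulation, feedback loops, measurement-specific noise (counts,
normalisation artefacts), and multifactorial perturbations. Passing
benchmarks therefore demonstrate correctness of the estimator under its
own model class, not robustness to real transcriptomic data.

## Evaluation

`evaluate.score_matrix` scores full off-diagonal matrices (both
triangles, so direction errors count). Positives are truth entries ≠ 0;
AUROC uses midrank tie handling (equal to the pairwise-comparison count
with half credit for ties, verified exactly against enumeration), AUPRC is
the step-wise average-precision sum, Spearman uses signed values with
midranks, MSE is the mean squared signed difference. Diagonals are
excluded by default (identically 1 in L, 0 in W, for truth and estimate
alike — pure padding); a flag restores them. Detection ranking uses
estimate magnitudes; a separate nonnegative ranking matrix can be supplied
when the ranking estimator (a magnitude average) differs from the signed
point estimate.

## Known limitations

- Ordering space grows as p!; with the unconstrained per-ordering weight
  solve (O(p⁶) overall) the method is practical for tens of genes only.
  Penalised (ridge/lasso) weight estimation and richer samplers (e.g.
  parallel tempering) are natural extensions, not implemented here.
- The complete-candidate-parent regression is near-collinear when σ is
  tiny relative to signal (smallest Gram eigenvalue ~σ²); coefficient
  errors then scale as ~1/√N irrespective of σ. Intervention-rich designs
  restore conditioning.
- Temperature auto-tuning optimises a flat objective; treat the tuned η
  as "a reasonable value", not a sharp optimum.
- The equivalence class of orderings compatible with a DAG is typically
  large; the position-frequency matrix, not a single ordering, is the
  honest summary of what the data determine.
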