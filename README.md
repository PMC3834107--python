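# ordercause

Joint estimation of causal gene-regulatory effects from an arbitrary mixture
of observational (wild-type) and intervention (knock-out / knock-down)
expression data.

## The problem

Expression data alone cannot orient regulatory edges: a Gaussian graphical
model fitted to wild-type samples yields an undirected (or
Markov-equivalent) structure, and the likelihood is provably invariant to
the causal ordering of the genes. Knock-out experiments break this
symmetry. `ordercause` models a gene network as a **causal Gaussian
Bayesian network**: each gene follows

    X_j = m_j + Σ_{i ∈ pa(j)} w_ij X_i + ε_j,     ε_j ~ N(0, σ_j²)

with acyclic direct effects `W = (w_ij)`. A hard intervention
do(X_J = x_J) severs the incoming edges of the clamped genes J and fixes
their values. Direct causal effects are the entries of `W`; total causal
effects are the entries of `L = (I − W)⁻¹ = I + W + … + W^{p−1}`
(sum over all directed paths).

Given data with per-sample intervention sets J_k, the log-likelihood of
θ = (m, σ, W) excludes the clamped residual terms:

    ℓ = −(log 2π / 2) Σ_j N_j − Σ_j N_j log σ_j
        − ½ Σ_k Σ_{j ∉ J_k} (x_j^k − x^k W e_jᵀ − m_j)² / σ_j²

where N_j counts the samples that do not clamp gene j. For a **fixed
causal ordering** the maximiser over (m, σ, W) is closed-form — one small
least-squares system per gene on data centred within its unclamped samples
— so the ordering's profile likelihood is cheap. A Metropolis–Hastings
chain then explores the space of causal orderings, proposing from a
**Mallows model** `P(O* | O) ∝ φ^{d(O*, O)}` (Kendall-tau distance d,
dispersion φ = exp(−1/η)), sampled exactly by repeated insertion. The
proposal is symmetric, so moves are accepted with probability
min(exp(ℓ* − ℓ), 1). Any intervention design is supported: none, partial,
complete single-gene, or multiple simultaneous knock-outs.

Because of the curse of dimensionality over orderings (and the O(p⁶) cost
of the unconstrained weight solve), the method targets small networks
(tens of genes), not genome-scale inference.

## Worked example

Simulate one benchmark dataset from the shipped 10-gene network (10
wild-types plus one knock-out per gene, σ = 0.1), fit the model, and score
the estimated effects against the generating network:

```python
import numpy as np
import ordercause as oc

skeleton = oc.benchmark_dag_skeleton()
dag = oc.random_weights(skeleton, seed=7)
params = oc.GbnParams(dag=dag, m=np.full(10, 0.5), sigma=np.full(10, 0.1))
design, _ = oc.benchmark_design("mixed", seed=7)
data = oc.sample_gbn(params, design, seed=8)

model = oc.CausalNetworkModel(data)
res = model.fit(n_iter=20_000, thin=50, eta="auto", seed=9)
print(res.summary())

scores = oc.score_matrix(oc.total_effect_matrix(dag), res.total_effects.to_numpy())
print(f"AUROC (total effects) vs truth: {scores.auroc:.3f}")
print(f"MSE   (total effects) vs truth: {scores.mse:.4f}")
```

```
                 Causal network ordering-MCMC results
=====================================================================
---------------------------------------------------------------------
               genes                                               10
             samples                                               20
intervention samples                                               10
             sampler                                          mallows
          iterations                                            20000
      burn-in / thin                                        2000 / 50
      kept orderings                                              360
     temperature eta                                             0.60
     acceptance rate                                            0.314
 best log-likelihood                                          209.262
best causal ordering N1 < N6 < N7 < N9 < N8 < N5 < N4 < N2 < N3 < N10
    effect estimator                                   posterior_mean
---------------------------------------------------------------------

AUROC (total effects) vs truth: 0.986
MSE   (total effects) vs truth: 0.0393
```

The summary reports the auto-tuned Mallows temperature (η = 0.6, chosen by
trial runs targeting 30–40% acceptance), the realised acceptance rate, the
best-likelihood causal ordering found, and the estimator used for the
effect matrices (`res.total_effects`, `res.direct_effects`). An AUROC of
0.986 means the 27 truly nonzero total effects among the 90 ordered gene
pairs are ranked almost perfectly above the zero ones;
`res.position_frequencies` gives the posterior distribution of each gene's
position in the causal ordering.

The same workflow is available from the shell:

```bash
ordercause simulate --preset mixed --sigma 0.1 --seed 7 --out sim/
ordercause run --data sim/X.tsv --design sim/design.tsv --iters 20000 \
               --burnin 2000 --eta auto --seed 9 --out fit/
ordercause evaluate --truth sim/true_dag.tsv --est fit/ --out metrics.json
```

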