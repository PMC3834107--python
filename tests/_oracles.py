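"""Independent oracle implementations used to validate the package.

Deliberately naive: per-node conditional densities, generic numerical
optimisation, exhaustive enumeration, pairwise counting.  None of them share
code with the implementation they check.
"""

import itertools
import math

import numpy as np
from scipy import optimize
from scipy.stats import norm

import ordercause as oc


def conditional_loglik(params, data):
    """Log-likelihood as a sum of per-node univariate conditional Gaussian
    densities, skipping clamped (sample, gene) pairs."""
    W = params.dag.W
    total = 0.0
    for k, assignment in enumerate(data.design.assignments):
        clamped = {data.labels.index(lab) for lab in assignment}
        x = data.X[k]
        for j in range(data.p):
            if j in clamped:
                continue
            mean = params.m[j] + x @ W[:, j]
            total += norm.logpdf(x[j], loc=mean, scale=params.sigma[j])
    return total


def brute_force_max_loglik(data, ordering, n_restarts=3, seed=0):
    """Numerically maximise the exact log-likelihood over (m, log sigma, W)
    with W supported on the complete DAG of the ordering."""
    ordering = np.asarray(ordering)
    p = data.p
    pairs = [(ordering[a], ordering[b]) for a in range(p) for b in range(a + 1, p)]

    def unpack(theta):
        m = theta[:p]
        sigma = np.exp(theta[p : 2 * p])
        W = np.zeros((p, p))
        for idx, (i, j) in enumerate(pairs):
            W[i, j] = theta[2 * p + idx]
        return m, sigma, W

    labels = data.labels

    def negloglik(theta):
        m, sigma, W = unpack(theta)
        dag = oc.WeightedDag(labels=labels, W=W)
        params = oc.GbnParams(dag=dag, m=m, sigma=sigma)
        return -oc.log_likelihood(params, data)

    rng = np.random.default_rng(seed)
    best = np.inf
    for r in range(n_restarts):
        x0 = np.concatenate(
            [
                data.X.mean(0) + 0.1 * rng.normal(size=p),
                np.log(data.X.std(0) + 0.1) + 0.1 * rng.normal(size=p),
                0.1 * rng.normal(size=len(pairs)),
            ]
        )
        res = optimize.minimize(
            negloglik, x0, method="Nelder-Mead",
            options={"maxiter": 40_000, "xatol": 1e-10, "fatol": 1e-12},
        )
        res = optimize.minimize(
            negloglik, res.x, method="Powell",
            options={"maxiter": 40_000, "xtol": 1e-12, "ftol": 1e-14},
        )
        best = min(best, res.fun)
    return -best


def kendall_brute(a, b):
    a, b = list(a), list(b)
    pos_a = {v: i for i, v in enumerate(a)}
    pos_b = {v: i for i, v in enumerate(b)}
    d = 0
    for u, v in itertools.combinations(a, 2):
        if (pos_a[u] - pos_a[v]) * (pos_b[u] - pos_b[v]) < 0:
            d += 1
    return d


def mallows_probs_exhaustive(ref, phi):
    """Exact Mallows probabilities over all permutations (tiny p only)."""
    perms = list(itertools.permutations(range(len(ref))))
    weights = np.array([phi ** kendall_brute(perm, ref) for perm in perms])
    return {perm: w for perm, w in zip(perms, weights / weights.sum())}


def auroc_pairwise(y, scores):
    """Mann–Whitney AUROC: fraction of positive/negative pairs ranked
    correctly, half credit for ties."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def finite_diff_grad(f, x, h=1e-6):
    g = np.zeros_like(x)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g
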