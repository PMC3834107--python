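"""Exact likelihood of mixed observational/knock-out data and its profile MLE.

For data ``x^k`` with intervention sets ``J_k`` (clamped genes), the
log-likelihood of theta = (m, sigma, W) is

    l = -(log 2pi / 2) sum_j N_j - sum_j N_j log sigma_j
        - 1/2 sum_k sum_{j not in J_k} (x_j^k - x^k W e_j' - m_j)^2 / sigma_j^2

where ``K_j = {k : j not in J_k}`` and ``N_j = |K_j|``: a clamped gene
contributes no residual term in the samples that clamp it.  Given a causal
ordering the maximum over (m, sigma, W) is available in closed form — per
target gene an ordinary least-squares system on data centred within K_j —
which makes the ordering's profile likelihood cheap enough to evaluate inside
an MCMC loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dag import WeightedDag
from .gbn import GbnParams
from .simulate import ExpressionDataset

__all__ = [
    "FitResult",
    "ProfileLikelihood",
    "log_likelihood",
    "profile_mean",
    "profile_weights",
    "profile_sigma",
    "max_log_likelihood",
    "SIGMA_FLOOR",
]

#: Numerical floor for fitted residual SDs; keeps the log-likelihood finite
#: on noiseless fixtures.
SIGMA_FLOOR = 1e-8

#: Relative rank tolerance for declaring a per-gene normal-equation system
#: degenerate.
RANK_RTOL = 1e-10


@dataclass
class FitResult:
    """Profile-MLE fit of a causal ordering.

    ``params`` carries (m-hat, sigma-hat, W-hat); entries of m/sigma for
    genes clamped in every sample are NaN (listed in ``undefined_genes``).
    ``degenerate_edges`` lists (parent, child) label pairs whose coefficient
    was not identifiable from the design (minimum-norm value returned).
    """

    params: GbnParams
    loglik: float
    ordering: np.ndarray
    degenerate_edges: set[tuple[str, str]] = field(default_factory=set)
    undefined_genes: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "loglik": self.loglik,
            "ordering": [self.params.labels[j] for j in self.ordering],
            "degenerate_edges": sorted(self.degenerate_edges),
            "undefined_genes": list(self.undefined_genes),
        }


def _clamp_mask(data: ExpressionDataset) -> np.ndarray:
    mask, _ = data.design.clamp_arrays(data.labels)
    return mask


def log_likelihood(params: GbnParams, data: ExpressionDataset) -> float:
    """Exact log-likelihood of ``params`` on ``data`` (clamp terms excluded).

    Uses the identity W_J e_j' = W e_j' for j not in J: the residual of a
    non-clamped gene has the same form whether or not its sample was an
    intervention, because clamping only severs edges *into* clamped genes.
    """
    if params.labels != data.labels:
        raise ValueError("parameter and dataset gene labels differ")
    mask = _clamp_mask(data)
    free = ~mask
    N_j = free.sum(axis=0)
    active = N_j > 0
    sigma = params.sigma
    bad = active & ~(np.nan_to_num(sigma, nan=-1.0) > 0)
    if np.any(bad):
        raise ValueError("sigma must be strictly positive for every modelled gene")
    resid = data.X - params.m - data.X @ params.dag.W
    with np.errstate(invalid="ignore", divide="ignore"):
        quad = np.where(free, resid**2 / sigma**2, 0.0)
        log_sigma = np.where(active, np.log(sigma, where=active, out=np.zeros_like(sigma)), 0.0)
    return float(
        -0.5 * np.log(2 * np.pi) * N_j.sum() - (N_j * log_sigma).sum() - 0.5 * quad.sum()
    )


class ProfileLikelihood:
    """Per-dataset cache for fast profile-likelihood fits of orderings.

    On construction the dataset is organised per target gene j: the rows
    K_j that do not clamp j, their mean, the centred block Y_j and its Gram
    matrix.  :meth:`fit` then solves, for each gene, the normal equations of
    the regression of gene j on the genes preceding it in the ordering
    (the complete DAG consistent with the ordering).
    """

    def __init__(self, data: ExpressionDataset):
        self.data = data
        self.labels = data.labels
        self.p = data.p
        mask = _clamp_mask(data)
        X = data.X
        self.N_j = (~mask).sum(axis=0).astype(int)
        self._mean: list[np.ndarray | None] = []
        self._Y: list[np.ndarray | None] = []
        self._G: list[np.ndarray | None] = []
        for j in range(self.p):
            rows = np.flatnonzero(~mask[:, j])
            if rows.size == 0:
                self._mean.append(None)
                self._Y.append(None)
                self._G.append(None)
                continue
            sub = X[rows]
            mean = sub.mean(axis=0)
            Y = sub - mean
            self._mean.append(mean)
            self._Y.append(Y)
            self._G.append(Y.T @ Y)
        self._const = -0.5 * np.log(2 * np.pi) * self.N_j.sum()
        # stacked Grams for the vectorised likelihood path; inactive genes
        # (N_j = 0) get an identity placeholder and contribute nothing
        self._Gstack = np.stack(
            [G if G is not None else np.eye(self.p) for G in self._G]
        )
        self._scale = np.array(
            [math.sqrt(G.diagonal().max()) if G is not None else 1.0 for G in self._G]
        )

    def fit(self, ordering: np.ndarray | list[int]) -> FitResult:
        """Closed-form (m, sigma, W) maximiser of the likelihood for one ordering."""
        order = _check_ordering(ordering, self.p)
        W, m, sigma, loglik, degenerate, undefined = self._fit_arrays(order)
        dag = WeightedDag(labels=list(self.labels), W=W)
        params = GbnParams(dag=dag, m=m, sigma=sigma)
        return FitResult(
            params=params,
            loglik=float(loglik),
            ordering=order,
            degenerate_edges=degenerate,
            undefined_genes=undefined,
        )

    def fit_loglik(self, ordering: np.ndarray | list[int]) -> float:
        """Maximised log-likelihood of an ordering without building the
        parameter objects — the fast path used inside the MCMC loop.

        For gene j at ordering position t, the residual sum of squares of
        its regression on the preceding genes is the squared (t+1)-th
        Cholesky pivot of the ordering-permuted Gram matrix G_j; one batched
        Cholesky over the stacked Grams yields every RSS at once.  Falls
        back to the per-node solver whenever a Gram is (near-)singular.
        """
        order = _check_ordering(ordering, self.p)
        p = self.p
        try:
            M = self._Gstack[:, order[:, None], order]
            C = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return float(self._fit_arrays(order)[3])
        diag = np.arange(p)
        piv = C[:, diag, diag]  # (gene j, ordering position)
        pos_of = np.empty(p, dtype=int)
        pos_of[order] = diag
        # slow path must agree when it would have taken the min-norm branch
        cummin = np.minimum.accumulate(piv, axis=1)
        relevant = cummin[diag, pos_of]
        if np.any(relevant <= math.sqrt(RANK_RTOL) * self._scale):
            return float(self._fit_arrays(order)[3])
        rss = piv[diag, pos_of] ** 2
        nj = self.N_j
        sigma = np.maximum(np.sqrt(rss / np.maximum(nj, 1)), SIGMA_FLOOR)
        active = nj > 0
        terms = -nj[active] * np.log(sigma[active]) - 0.5 * rss[active] / sigma[active] ** 2
        return float(self._const + terms.sum())

    def _fit_arrays(self, order: np.ndarray):
        p = self.p
        W = np.zeros((p, p))
        m = np.full(p, np.nan)
        sigma = np.full(p, np.nan)
        degenerate: set[tuple[str, str]] = set()
        undefined: list[str] = []
        loglik = self._const
        for pos in range(p):
            j = order[pos]
            nj = self.N_j[j]
            if nj == 0:
                undefined.append(self.labels[j])
                continue
            parents = order[:pos]
            Y = self._Y[j]
            G = self._G[j]
            if parents.size:
                A = G[parents[:, None], parents]
                b = G[parents, j]
                w, deg_idx = _solve_normal_equations(A, b)
                if deg_idx is not None:
                    for i in parents[deg_idx]:
                        degenerate.add((self.labels[i], self.labels[j]))
                W[parents, j] = w
                r = Y[:, j] - Y[:, parents] @ w
            else:
                r = Y[:, j]
            rss = float(r @ r)
            sj = max(math.sqrt(rss / nj), SIGMA_FLOOR)
            sigma[j] = sj
            mean = self._mean[j]
            m[j] = mean[j] - mean @ W[:, j]
            loglik += -nj * math.log(sj) - 0.5 * rss / (sj * sj)
        return W, m, sigma, loglik, degenerate, undefined


def _check_ordering(ordering, p: int) -> np.ndarray:
    order = np.asarray(ordering, dtype=int).ravel()
    if order.shape != (p,) or not np.array_equal(np.sort(order), np.arange(p)):
        raise ValueError(f"ordering must be a permutation of 0..{p - 1}")
    return order


def _solve_normal_equations(A: np.ndarray, b: np.ndarray):
    """Solve A w = b; Cholesky fast path, minimum-norm pseudo-inverse when the
    system is (numerically) rank-deficient.  Returns (w, degenerate_index)
    where degenerate_index selects the coefficients lying in the null space
    (None when fully determined)."""
    try:
        C = np.linalg.cholesky(A)
        # reject ill-conditioned factorisations: tiny pivot relative to scale
        scale = math.sqrt(max(A.diagonal().max(), 0.0))
        if scale > 0 and C.diagonal().min() > math.sqrt(RANK_RTOL) * scale:
            return np.linalg.solve(A, b), None
    except np.linalg.LinAlgError:
        pass
    # degenerate (or nearly so): minimum-norm least squares + null-space report
    U, s, Vt = np.linalg.svd(A, hermitian=True)
    tol = RANK_RTOL * (s[0] if s.size else 0.0)
    keep = s > tol
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    w = Vt.T @ (s_inv * (U.T @ b))
    if np.all(keep):
        return w, None
    null = Vt[~keep]  # rows span the null space
    involved = np.flatnonzero(np.abs(null).max(axis=0) > 1e-8)
    return w, involved


# --------------------------------------------------------------------------
# free-standing operations (thin wrappers over ProfileLikelihood)


def profile_weights(
    data: ExpressionDataset, ordering
) -> tuple[np.ndarray, set[tuple[str, str]]]:
    """Closed-form W-hat for an ordering: per gene j, least squares of gene j
    on all preceding genes over the samples K_j (centred within K_j)."""
    fit = ProfileLikelihood(data).fit(ordering)
    return fit.params.dag.W, fit.degenerate_edges


def profile_mean(data: ExpressionDataset, W: np.ndarray, ordering=None) -> np.ndarray:
    """Closed-form m-hat given W: the K_j-mean of ``x_j - x W e_j'`` per gene;
    NaN for genes clamped in every sample."""
    pl = ProfileLikelihood(data)
    m = np.full(data.p, np.nan)
    for j in range(data.p):
        if pl.N_j[j] == 0:
            continue
        mean = pl._mean[j]
        m[j] = mean[j] - mean @ W[:, j]
    return m


def profile_sigma(data: ExpressionDataset, W: np.ndarray, ordering=None) -> np.ndarray:
    """Closed-form sigma-hat given W: RMS of the centred residuals over K_j
    (1/N_j normalisation), floored at SIGMA_FLOOR; NaN when N_j = 0."""
    pl = ProfileLikelihood(data)
    sigma = np.full(data.p, np.nan)
    for j in range(data.p):
        if pl.N_j[j] == 0:
            continue
        Y = pl._Y[j]
        r = Y[:, j] - Y @ W[:, j]
        sigma[j] = max(np.sqrt(float(r @ r) / pl.N_j[j]), SIGMA_FLOOR)
    return sigma


def max_log_likelihood(data: ExpressionDataset, ordering) -> FitResult:
    """Profile MLE of (m, sigma, W) for one causal ordering.

    This maximised likelihood is the target density pi(.) of the
    Metropolis–Hastings sampler over orderings.
    """
    return ProfileLikelihood(data).fit(ordering)
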