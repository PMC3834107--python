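"""Gaussian Bayesian network parameters and their exact Gaussian laws.

The structural model for a sample row-vector ``X = (X_1, ..., X_p)`` is

    X_j = m_j + sum_{i in pa(j)} w_ij X_i + eps_j,   eps_j ~ N(0, sigma_j^2)

with independent residuals, i.e. in matrix form ``X = m + X W + eps`` and,
by nilpotence of W, ``X = m L + eps L`` with ``L = (I - W)^{-1}``.  The joint
law is therefore multivariate normal, both observationally and under any
hard intervention do(X_J = x_J), which severs the incoming edges of J and
fixes those coordinates deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .dag import WeightedDag, total_effect_matrix

__all__ = ["GbnParams", "GaussianLaw", "observational_law", "intervention_law"]


@dataclass
class GbnParams:
    """Full parameter vector theta = (m, sigma, W) of a Gaussian network.

    ``m`` are the residual means, ``sigma`` the residual standard deviations
    (strictly positive) and the weights live in ``dag.W``.
    """

    dag: WeightedDag
    m: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float).ravel()
        self.sigma = np.asarray(self.sigma, dtype=float).ravel()
        p = self.dag.p
        if self.m.shape != (p,) or self.sigma.shape != (p,):
            raise ValueError("m and sigma must have one entry per gene")
        # NaN marks components a profile fit could not identify (gene clamped
        # in every sample); finite entries must be strictly positive
        if not np.all((self.sigma > 0) | np.isnan(self.sigma)):
            raise ValueError("sigma must be strictly positive")

    @property
    def p(self) -> int:
        return self.dag.p

    @property
    def labels(self) -> list[str]:
        return self.dag.labels


@dataclass
class GaussianLaw:
    """A multivariate normal law over the full gene vector.

    Under an intervention the clamped coordinates are deterministic: their
    rows and columns of ``cov`` are identically zero and their means equal
    the clamp values.
    """

    mu: np.ndarray
    cov: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (self.mu.size, self.mu.size):
            raise ValueError("cov shape does not match mu")


def observational_law(params: GbnParams) -> GaussianLaw:
    """Exact joint law without interventions: N(mL, L' diag(sigma^2) L)."""
    L = total_effect_matrix(params.dag)
    mu = params.m @ L
    cov = L.T @ np.diag(params.sigma**2) @ L
    return GaussianLaw(mu=mu, cov=cov)


def _clamp_indices(dag: WeightedDag, clamp: Mapping[str, float] | Iterable[str]) -> dict[int, float]:
    """Normalise a clamp specification to {node index: value}; default value 0
    (knock-out) when only labels are given."""
    if isinstance(clamp, Mapping):
        items = clamp.items()
    else:
        items = ((lab, 0.0) for lab in clamp)
    return {dag.index(lab): float(v) for lab, v in items}


def intervention_law(
    params: GbnParams,
    clamp: Mapping[str, float] | Iterable[str],
) -> GaussianLaw:
    """Joint law of the full gene vector under do(X_J = x_J).

    ``clamp`` maps gene labels to clamp values (an iterable of labels clamps
    to 0, the knock-out convention).  The intervention replaces W by W_J —
    all incoming edges of J removed — and the residual-mean vector by
    nu_J, which carries the clamp value for j in J and m_j otherwise:

        mu_J = nu_J L_J,   Sigma_J = sum_{j not in J} sigma_j^2 L_J' e_j' e_j L_J

    so clamped coordinates have exact mean x_j and zero variance.
    """
    jmap = _clamp_indices(params.dag, clamp)
    if not jmap:
        return observational_law(params)
    p = params.p
    J = np.fromiter(jmap.keys(), dtype=int)
    WJ = params.dag.W.copy()
    WJ[:, J] = 0.0
    dag_J = WeightedDag(labels=params.labels, W=WJ)  # subgraph of an acyclic graph
    LJ = total_effect_matrix(dag_J)
    nu = params.m.copy()
    nu[J] = [jmap[j] for j in J]
    var = params.sigma**2
    var = var.copy()
    var[J] = 0.0
    mu = nu @ LJ
    cov = LJ.T @ np.diag(var) @ LJ
    return GaussianLaw(mu=mu, cov=cov)
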