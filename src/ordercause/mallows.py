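"""Mallows distribution over causal orderings.

The proposal density over permutations is ``P(O* | O, phi) = phi^d(O*, O) / Z``
with Kendall-tau distance ``d`` (number of pairwise ranking disagreements)
and dispersion ``phi = exp(-1/eta)`` for a temperature ``eta > 0``.  The
normalising constant has the closed Kendall form

    Z(phi, p) = prod_{i=1}^{p} (1 + phi + ... + phi^{i-1}).

``phi = 1`` gives the uniform distribution over permutations and ``phi -> 0``
a point mass on the reference ordering; sharp proposals therefore correspond
to small temperatures.  Exact sampling uses the repeated insertion model
(RIM): the item at reference rank i is inserted at position j <= i with
probability ``phi^{i-j} / (1 + phi + ... + phi^{i-1})``, independently
across i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MallowsConfig",
    "kendall_distance",
    "mallows_log_density",
    "sample_mallows",
    "log_normalizer",
    "expected_distance",
]


@dataclass(frozen=True)
class MallowsConfig:
    """Temperature parameterisation of the Mallows dispersion."""

    eta: float

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise ValueError("eta must be positive")

    @property
    def phi(self) -> float:
        return float(np.exp(-1.0 / self.eta))


def _as_perm(o) -> np.ndarray:
    a = np.asarray(o, dtype=int).ravel()
    if not np.array_equal(np.sort(a), np.arange(a.size)):
        raise ValueError("not a permutation of 0..p-1")
    return a


def kendall_distance(a, b) -> int:
    """Number of unordered pairs ranked oppositely by the two orderings."""
    a, b = _as_perm(a), _as_perm(b)
    if a.size != b.size:
        raise ValueError("orderings have different lengths")
    pos_b = np.empty(a.size, dtype=int)
    pos_b[b] = np.arange(a.size)
    seq = pos_b[a]  # b-positions visited in a-order; inversions = disagreements
    # O(p^2) pair count; p is small (network sizes of tens)
    return int(np.triu(seq[:, None] > seq[None, :], k=1).sum())


def log_normalizer(phi: float, p: int) -> float:
    """log Z(phi, p) of the Kendall–Mallows model."""
    if not 0 < phi <= 1:
        raise ValueError("phi must lie in (0, 1]")
    i = np.arange(1, p + 1)
    if phi == 1.0:
        return float(np.sum(np.log(i)))  # Z = p!
    return float(np.sum(np.log1p(-(phi**i)) - np.log1p(-phi)))


def mallows_log_density(o, ref, cfg: MallowsConfig) -> float:
    """log P(o | ref, phi) = d(o, ref) log phi - log Z(phi, p).

    Symmetric in (o, ref) because the Kendall distance is — the property
    that cancels the proposal terms in the Metropolis–Hastings ratio.
    """
    o, ref = _as_perm(o), _as_perm(ref)
    phi = cfg.phi
    d = kendall_distance(o, ref)
    return d * np.log(phi) - log_normalizer(phi, o.size)


def sample_mallows(ref, cfg: MallowsConfig, seed: int | np.random.Generator) -> np.ndarray:
    """Draw one ordering exactly from the Mallows law centred at ``ref``.

    Repeated insertion: build the permutation by inserting ref's items in
    rank order; inserting the i-th item j-1 slots before the end contributes
    j-1 pairwise disagreements, with probability proportional to phi^{j-1}.
    """
    ref = _as_perm(ref)
    rng = np.random.default_rng(seed)
    phi = cfg.phi
    p = ref.size
    out: list[int] = []
    for i in range(1, p + 1):
        # insertion offsets 0..i-1 from the end, weight phi^offset
        weights = phi ** np.arange(i, dtype=float)
        cdf = np.cumsum(weights)
        u = rng.random() * cdf[-1]
        offset = int(np.searchsorted(cdf, u, side="right"))
        offset = min(offset, i - 1)
        out.insert(len(out) - offset, int(ref[i - 1]))
    return np.asarray(out, dtype=int)


def expected_distance(phi: float, p: int) -> float:
    """Closed-form mean Kendall distance under Mallows(phi, p):
    sum_{i=1}^{p} [ phi/(1-phi) - i phi^i / (1-phi^i) ]."""
    if phi == 1.0:
        return p * (p - 1) / 4.0
    i = np.arange(1, p + 1)
    return float(np.sum(phi / (1 - phi) - i * phi**i / (1 - phi**i)))
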