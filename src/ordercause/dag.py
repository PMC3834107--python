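"""Weighted directed acyclic graphs of direct causal effects.

A gene network is encoded by a weight matrix ``W`` where ``W[i, j]`` is the
direct (per-unit) effect of gene ``i`` on gene ``j`` — the coefficient of
``X_i`` in the linear structural equation for ``X_j``.  The induced total
effects are the entries of ``L = (I - W)^{-1}``, which for an acyclic graph
is the finite Neumann series ``I + W + ... + W^{p-1}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "WeightedDag",
    "CyclicGraphError",
    "total_effect_matrix",
    "direct_effect_matrix",
]


class CyclicGraphError(ValueError):
    """Raised when a weight matrix contains a directed cycle."""


@dataclass
class WeightedDag:
    """An acyclic, edge-weighted directed graph over labelled genes.

    Parameters
    ----------
    labels
        Gene names, one per node; fixes the row/column order of ``W``.
    W
        ``p x p`` matrix of direct-effect weights; ``W[i, j] != 0`` iff the
        graph has the edge ``i -> j``.
    """

    labels: list[str]
    W: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        p = len(self.labels)
        if self.W.shape != (p, p):
            raise ValueError(f"W must be {p}x{p}, got {self.W.shape}")
        if len(set(self.labels)) != p:
            raise ValueError("gene labels must be unique")
        self._topo_order = _topological_order(self.W)

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        """Edge list as (source, target, weight) triples."""
        ii, jj = np.nonzero(self.W)
        return [(self.labels[i], self.labels[j], self.W[i, j]) for i, j in zip(ii, jj)]

    @property
    def topological_order(self) -> np.ndarray:
        """A parental order: node indices such that every edge points forward."""
        return self._topo_order.copy()

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown gene label {label!r}") from None

    def ancestor_matrix(self) -> np.ndarray:
        """Boolean matrix; entry (i, j) true iff i is a proper ancestor of j."""
        g = nx.from_numpy_array(self.W != 0, create_using=nx.DiGraph)
        anc = np.zeros((self.p, self.p), dtype=bool)
        for j in range(self.p):
            for i in nx.ancestors(g, j):
                anc[i, j] = True
        return anc

    # ------------------------------------------------------------------ I/O

    def to_edge_tsv(self, path) -> None:
        """Write the edge list as ``source<TAB>target<TAB>weight`` with header."""
        df = pd.DataFrame(self.edges, columns=["source", "target", "weight"])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_edge_tsv(cls, path, labels: list[str] | None = None) -> "WeightedDag":
        """Read an edge-list TSV; node set is the union of endpoints unless given."""
        df = pd.read_csv(path, sep="\t", comment="#")
        if labels is None:
            seen: dict[str, None] = {}
            for col in ("source", "target"):
                for lab in df[col].astype(str):
                    seen.setdefault(lab, None)
            labels = list(seen)
        idx = {lab: k for k, lab in enumerate(labels)}
        W = np.zeros((len(labels), len(labels)))
        for _, row in df.iterrows():
            W[idx[str(row["source"])], idx[str(row["target"])]] = row["weight"]
        return cls(labels=labels, W=W)

    def to_matrix_csv(self, path) -> None:
        """Write the full W matrix as a labelled CSV."""
        pd.DataFrame(self.W, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_matrix_csv(cls, path) -> "WeightedDag":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=[str(c) for c in df.columns], W=df.to_numpy())


def _topological_order(W: np.ndarray) -> np.ndarray:
    """Topological order of the support of W; raises on cycles."""
    g = nx.from_numpy_array(W != 0, create_using=nx.DiGraph)
    try:
        return np.fromiter(nx.topological_sort(g), dtype=int, count=W.shape[0])
    except nx.NetworkXUnfeasible:
        raise CyclicGraphError("weight matrix contains a directed cycle") from None


def total_effect_matrix(dag: WeightedDag) -> np.ndarray:
    """Total causal effects ``L = (I - W)^{-1} = I + W + ... + W^{p-1}``.

    Entry ``(i, j)`` with ``i != j`` is the total effect of gene ``i`` on
    gene ``j`` — the sum over all directed paths of the products of edge
    weights; it vanishes exactly when ``i`` is not an ancestor of ``j``.
    The diagonal is identically 1.

    Computed by a triangular solve in topological order (W permuted to
    strictly upper triangular form), which is exact for acyclic W.
    """
    order = dag._topo_order  # validated acyclic at construction
    p = dag.p
    Wp = dag.W[np.ix_(order, order)]
    # (I - Wp) is unit upper triangular; solve (I - Wp) Lp = I column-wise
    from scipy.linalg import solve_triangular

    Lp = solve_triangular(np.eye(p) - Wp, np.eye(p), unit_diagonal=True)
    inv = np.empty(p, dtype=int)
    inv[order] = np.arange(p)
    return Lp[np.ix_(inv, inv)]


def neumann_series(W: np.ndarray) -> np.ndarray:
    """Truncated power series ``I + W + ... + W^{p-1}``; equals
    :func:`total_effect_matrix` for acyclic W (cross-check route)."""
    p = W.shape[0]
    L = np.eye(p)
    term = np.eye(p)
    for _ in range(p - 1):
        term = term @ W
        L += term
    return L


def direct_effect_matrix(dag: WeightedDag) -> np.ndarray:
    """Direct causal effects: the weight matrix W itself (named accessor)."""
    return dag.W.copy()
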