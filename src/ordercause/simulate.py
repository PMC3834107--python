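"""Synthetic expression data from a Gaussian network under intervention designs.

Implements the benchmark study conditions: a 10-gene, 21-edge network,
residual means 0.5, residual standard deviations in {0.01, 0.1, 0.5}, edge
weights drawn uniformly from (-1, -0.25) U (0.25, 1), and five intervention
designs ranging from purely observational to multiple knock-outs with hidden
genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dag import WeightedDag
from .gbn import GbnParams

__all__ = [
    "InterventionDesign",
    "ExpressionDataset",
    "benchmark_dag_skeleton",
    "random_weights",
    "sample_gbn",
    "benchmark_design",
    "mask_hidden",
    "BENCHMARK_DESIGNS",
    "RESIDUAL_MEAN",
    "SIGMA_SETTINGS",
]

#: Residual mean shared by every gene in the benchmark.
RESIDUAL_MEAN = 0.5
#: The three benchmark noise settings (small, moderate, large).
SIGMA_SETTINGS = (0.01, 0.1, 0.5)

PARTIAL_KO_GENES = ("N1", "N4", "N6", "N7", "N9")
DOUBLE_KO_PAIRS = (
    ("N1", "N5"),
    ("N1", "N6"),
    ("N4", "N7"),
    ("N6", "N9"),
    ("N7", "N10"),
)

BENCHMARK_DESIGNS = (
    "observational",
    "mixed",
    "partial_ko",
    "multiple_ko",
    "multiple_ko_hidden",
)


@dataclass
class InterventionDesign:
    """Per-sample clamp sets.

    ``assignments[k]`` maps the gene labels clamped in sample ``k`` to their
    clamp values; an empty mapping marks a wild-type (observational) sample.
    """

    assignments: list[dict[str, float]]

    @property
    def n_samples(self) -> int:
        return len(self.assignments)

    def validate(self, labels: Sequence[str]) -> None:
        known = set(labels)
        for k, a in enumerate(self.assignments):
            unknown = set(a) - known
            if unknown:
                raise KeyError(f"sample {k} clamps unknown gene(s) {sorted(unknown)}")

    def clamp_arrays(self, labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Boolean N x p clamp mask and matching clamp-value matrix."""
        idx = {lab: j for j, lab in enumerate(labels)}
        mask = np.zeros((self.n_samples, len(labels)), dtype=bool)
        values = np.zeros((self.n_samples, len(labels)))
        for k, a in enumerate(self.assignments):
            for lab, v in a.items():
                mask[k, idx[lab]] = True
                values[k, idx[lab]] = v
        return mask, values

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path) -> None:
        rows = []
        for k, a in enumerate(self.assignments):
            if a:
                genes = ",".join(a)
                vals = ",".join(repr(float(v)) for v in a.values())
            else:
                genes = vals = "-"
            rows.append((k, genes, vals))
        pd.DataFrame(rows, columns=["sample_id", "clamped_genes", "clamp_values"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "InterventionDesign":
        df = pd.read_csv(path, sep="\t", dtype=str).sort_values("sample_id", key=lambda s: s.astype(int))
        assignments: list[dict[str, float]] = []
        for _, row in df.iterrows():
            if row["clamped_genes"] in ("-", "", None) or pd.isna(row["clamped_genes"]):
                assignments.append({})
            else:
                genes = str(row["clamped_genes"]).split(",")
                vals = [float(v) for v in str(row["clamp_values"]).split(",")]
                assignments.append(dict(zip(genes, vals)))
        return cls(assignments=assignments)

    @classmethod
    def observational(cls, n: int) -> "InterventionDesign":
        return cls(assignments=[{} for _ in range(n)])


@dataclass
class ExpressionDataset:
    """An N x p expression matrix paired with its intervention design."""

    X: np.ndarray = field(repr=False)
    design: InterventionDesign
    labels: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape != (self.design.n_samples, len(self.labels)):
            raise ValueError(
                f"X shape {self.X.shape} inconsistent with design "
                f"({self.design.n_samples} samples) and {len(self.labels)} genes"
            )
        self.design.validate(self.labels)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.labels)

    def write(self, data_path, design_path) -> None:
        self.to_frame().to_csv(data_path, sep="\t", index=False)
        self.design.to_tsv(design_path)

    @classmethod
    def read(cls, data_path, design_path=None) -> "ExpressionDataset":
        with open(data_path) as fh:
            sep = "\t" if "\t" in fh.readline() else ","
        df = pd.read_csv(data_path, sep=sep, float_precision="round_trip")
        labels = [str(c) for c in df.columns]
        if design_path is None:
            design = InterventionDesign.observational(len(df))
        else:
            design = InterventionDesign.from_tsv(design_path)
        return cls(X=df.to_numpy(dtype=float), design=design, labels=labels)


# --------------------------------------------------------------------------
# benchmark network and weight sampling


def benchmark_dag_skeleton() -> WeightedDag:
    """The shipped synthetic 10-gene, 21-edge benchmark network.

    A reconstruction built to the documented structural constraints of the
    benchmark graph (root/sink admissible order positions); weights in the
    file are placeholders — draw per-dataset weights with
    :func:`random_weights`.
    """
    labels = [f"N{i}" for i in range(1, 11)]
    ref = resources.files("ordercause.data") / "benchmark_dag_synthetic.tsv"
    with resources.as_file(ref) as path:
        return WeightedDag.from_edge_tsv(path, labels=labels)


def random_weights(
    skeleton: WeightedDag | Iterable[tuple[str, str]],
    seed: int | np.random.Generator,
    labels: Sequence[str] | None = None,
) -> WeightedDag:
    """Draw edge weights uniformly from (-1, -0.25) U (0.25, 1).

    Magnitudes are uniform on (0.25, 1) with an independent fair sign, so the
    support excludes near-zero effects.  Accepts a :class:`WeightedDag`
    (its edge set is reused) or an explicit edge list.
    """
    rng = np.random.default_rng(seed)
    if isinstance(skeleton, WeightedDag):
        dag_labels = list(skeleton.labels)
        edges = [(s, t) for s, t, _ in skeleton.edges]
    else:
        edges = [(s, t) for s, t in skeleton]
        if labels is None:
            seen: dict[str, None] = {}
            for s, t in edges:
                seen.setdefault(s, None)
                seen.setdefault(t, None)
            dag_labels = list(seen)
        else:
            dag_labels = list(labels)
    idx = {lab: k for k, lab in enumerate(dag_labels)}
    W = np.zeros((len(dag_labels), len(dag_labels)))
    mags = rng.uniform(0.25, 1.0, size=len(edges))
    signs = rng.choice([-1.0, 1.0], size=len(edges))
    for (s, t), w in zip(edges, mags * signs):
        W[idx[s], idx[t]] = w
    return WeightedDag(labels=dag_labels, W=W)  # raises if the skeleton is cyclic


# --------------------------------------------------------------------------
# sampling from the structural equations


def sample_gbn(
    params: GbnParams,
    design: InterventionDesign,
    seed: int | np.random.Generator,
) -> ExpressionDataset:
    """Simulate one sample per design entry from the structural equations.

    Nodes are visited in topological order; clamped nodes take their clamp
    value exactly, all others are ``m_j + sum_i w_ij x_i + eps_j`` with
    independent Gaussian residuals.  Deterministic given the seed.
    """
    design.validate(params.labels)
    rng = np.random.default_rng(seed)
    N, p = design.n_samples, params.p
    mask, values = design.clamp_arrays(params.labels)
    order = params.dag.topological_order
    W = params.dag.W
    eps = rng.normal(0.0, params.sigma, size=(N, p))  # scaled per column
    X = np.zeros((N, p))
    for j in order:
        xj = params.m[j] + X @ W[:, j] + eps[:, j]
        X[:, j] = np.where(mask[:, j], values[:, j], xj)
    return ExpressionDataset(X=X, design=design, labels=list(params.labels))


# --------------------------------------------------------------------------
# benchmark intervention designs


def benchmark_design(
    name: str,
    seed: int | np.random.Generator = 0,
    labels: Sequence[str] | None = None,
) -> tuple[InterventionDesign, list[str]]:
    """One of the five benchmark designs on the 10-gene network.

    ========================  =============================================
    observational             20 wild-type replicates
    mixed                     10 wild-types + one knock-out per gene
    partial_ko                15 wild-types + knock-outs of N1,N4,N6,N7,N9
    multiple_ko               mixed + five double knock-outs
    multiple_ko_hidden        multiple_ko; additionally returns 3 genes
                              (chosen by ``seed``) to hide post-simulation
    ========================  =============================================

    Returns the design and the list of hidden gene labels (empty for all
    designs except ``multiple_ko_hidden``).
    """
    if labels is None:
        labels = [f"N{i}" for i in range(1, 11)]
    labels = list(labels)
    wt: dict[str, float] = {}

    def ko(*genes: str) -> dict[str, float]:
        return {g: 0.0 for g in genes}

    if name == "observational":
        assignments = [dict(wt) for _ in range(20)]
        hidden: list[str] = []
    elif name == "mixed":
        assignments = [dict(wt) for _ in range(10)] + [ko(g) for g in labels]
        hidden = []
    elif name == "partial_ko":
        assignments = [dict(wt) for _ in range(15)] + [ko(g) for g in PARTIAL_KO_GENES]
        hidden = []
    elif name in ("multiple_ko", "multiple_ko_hidden"):
        assignments = (
            [dict(wt) for _ in range(10)]
            + [ko(g) for g in labels]
            + [ko(a, b) for a, b in DOUBLE_KO_PAIRS]
        )
        if name == "multiple_ko_hidden":
            rng = np.random.default_rng(seed)
            hidden = sorted(rng.choice(labels, size=3, replace=False).tolist())
        else:
            hidden = []
    else:
        raise ValueError(f"unknown design {name!r}; choose from {BENCHMARK_DESIGNS}")
    return InterventionDesign(assignments=assignments), hidden


def mask_hidden(
    data: ExpressionDataset,
    hidden_labels: Iterable[str],
    drop_hidden_ko_samples: bool = False,
) -> ExpressionDataset:
    """Restrict a dataset to its observed genes.

    Hidden columns are removed and clamps of hidden genes are struck from the
    design — the intervention happened but is no longer recorded, so a sample
    that knocked out only hidden genes becomes (apparently) observational.
    With ``drop_hidden_ko_samples`` those samples are removed instead.
    """
    hidden = set(hidden_labels)
    unknown = hidden - set(data.labels)
    if unknown:
        raise KeyError(f"hidden labels not in dataset: {sorted(unknown)}")
    keep = [j for j, lab in enumerate(data.labels) if lab not in hidden]
    if not keep:
        raise ValueError("cannot hide every gene")
    rows, assignments = [], []
    for k, a in enumerate(data.design.assignments):
        if drop_hidden_ko_samples and any(lab in hidden for lab in a):
            continue
        rows.append(k)
        assignments.append({lab: v for lab, v in a.items() if lab not in hidden})
    return ExpressionDataset(
        X=data.X[np.ix_(rows, keep)],
        design=InterventionDesign(assignments=assignments),
        labels=[data.labels[j] for j in keep],
    )


def write_manifest(path, **entries) -> None:
    """Record run provenance (seeds, sigma, design, hidden genes) as JSON."""
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, default=str)
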