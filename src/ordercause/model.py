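"""Model/Results interface over the ordering-MCMC machinery.

`CausalNetworkModel` wraps an expression matrix plus its intervention design;
``fit()`` runs the Metropolis–Hastings search over causal orderings and
returns a `CausalNetworkResults` carrying the estimated network, effect
matrices, posterior diagnostics and a text summary, in the style of the
classic statistical-modelling packages.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .likelihood import log_likelihood
from .mcmc import McmcConfig, PosteriorSummary, estimate_effects, run_chain
from .simulate import ExpressionDataset, InterventionDesign

__all__ = ["CausalNetworkModel", "CausalNetworkResults"]


class CausalNetworkModel:
    """Causal Gaussian network model for mixed observational/knock-out data.

    Parameters
    ----------
    data
        Expression dataset (samples x genes) with its intervention design.

    Examples
    --------
    >>> model = CausalNetworkModel.from_dataframe(df, interventions=[{}, {"N1": 0.0}])
    >>> res = model.fit(n_iter=20_000, seed=1)
    >>> res.total_effects  # doctest: +SKIP
    """

    def __init__(self, data: ExpressionDataset):
        self.data = data

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        interventions: Sequence[Mapping[str, float]] | InterventionDesign | None = None,
    ) -> "CausalNetworkModel":
        """Build from a genes-in-columns DataFrame and per-row clamp mappings.

        ``interventions[k]`` maps gene names clamped in row ``k`` to their
        clamp values ({} = wild-type row); omit for purely observational data.
        """
        labels = [str(c) for c in frame.columns]
        if interventions is None:
            design = InterventionDesign.observational(len(frame))
        elif isinstance(interventions, InterventionDesign):
            design = interventions
        else:
            design = InterventionDesign(assignments=[dict(a) for a in interventions])
        return cls(ExpressionDataset(X=frame.to_numpy(dtype=float), design=design, labels=labels))

    @classmethod
    def from_files(cls, data_path, design_path=None) -> "CausalNetworkModel":
        return cls(ExpressionDataset.read(data_path, design_path))

    @property
    def is_observational(self) -> bool:
        return all(not a for a in self.data.design.assignments)

    def fit(
        self,
        n_iter: int = 50_000,
        burn_in: int | None = None,
        thin: int = 50,
        eta: float | str = "auto",
        mode: str | None = None,
        seed: int = 0,
        estimator: str = "posterior_mean",
    ) -> "CausalNetworkResults":
        """Run the ordering MCMC and return the fitted results.

        ``mode`` defaults to the Mallows sampler, or to uniform ordering
        sampling when the design is purely observational (where the
        likelihood is invariant to the ordering and cannot guide the chain).
        ``burn_in`` defaults to 10% of ``n_iter``.
        """
        if mode is None:
            mode = "uniform" if self.is_observational else "mallows"
        if burn_in is None:
            burn_in = n_iter // 10
        cfg = McmcConfig(
            n_iter=n_iter, burn_in=burn_in, thin=thin, eta=eta, mode=mode, seed=seed
        )
        summary = run_chain(self.data, cfg)
        return CausalNetworkResults(self, cfg, summary, estimator)


class CausalNetworkResults:
    """Fitted causal network: estimates, uncertainties and diagnostics."""

    def __init__(
        self,
        model: CausalNetworkModel,
        config: McmcConfig,
        posterior: PosteriorSummary,
        estimator: str = "best",
    ):
        self.model = model
        self.config = config
        self.posterior = posterior
        self.estimator = estimator
        self._L, self._W = estimate_effects(posterior, estimator=estimator)

    # ------------------------------------------------------------ estimates

    @property
    def labels(self) -> list[str]:
        return self.posterior.labels

    @property
    def params(self):
        """Best-likelihood parameter estimates (m-hat, sigma-hat, W-hat)."""
        return self.posterior.best_fit.params

    @property
    def loglik(self) -> float:
        return self.posterior.best_fit.loglik

    @property
    def ordering(self) -> list[str]:
        """Best-likelihood causal ordering, as gene labels."""
        return [self.labels[j] for j in self.posterior.best_fit.ordering]

    @property
    def total_effects(self) -> pd.DataFrame:
        """Estimated total causal effects; entry (i, j) = effect of i on j."""
        return pd.DataFrame(self._L, index=self.labels, columns=self.labels)

    @property
    def direct_effects(self) -> pd.DataFrame:
        """Estimated direct causal effects (the fitted weight matrix)."""
        return pd.DataFrame(self._W, index=self.labels, columns=self.labels)

    @property
    def position_frequencies(self) -> pd.DataFrame:
        """Posterior node-by-position frequencies (rows sum to one)."""
        p = len(self.labels)
        return pd.DataFrame(
            self.posterior.position_matrix,
            index=self.labels,
            columns=[f"pos{t + 1}" for t in range(p)],
        )

    def recomputed_loglik(self) -> float:
        """Log-likelihood of the best-fit parameters, recomputed from scratch."""
        return log_likelihood(self.params, self.model.data)

    # ---------------------------------------------------------- diagnostics

    def summary(self) -> SimpleTable:
        """Text summary: run settings, diagnostics and the causal ordering."""
        post = self.posterior
        rows = [
            ("genes", str(len(self.labels))),
            ("samples", str(self.model.data.n_samples)),
            ("intervention samples", str(sum(bool(a) for a in self.model.data.design.assignments))),
            ("sampler", self.config.mode),
            ("iterations", str(self.config.n_iter)),
            ("burn-in / thin", f"{self.config.burn_in} / {self.config.thin}"),
            ("kept orderings", str(len(post.kept_orderings))),
            ("temperature eta", "-" if post.eta_used is None else f"{post.eta_used:.2f}"),
            ("acceptance rate", f"{post.acceptance_rate:.3f}"),
            ("best log-likelihood", f"{self.loglik:.3f}"),
            ("best causal ordering", " < ".join(self.ordering)),
            ("effect estimator", self.estimator),
        ]
        return SimpleTable(
            [[k, v] for k, v in rows],
            headers=["", ""],
            title="Causal network ordering-MCMC results",
        )

    def plot_position_heatmap(self, ax=None):
        """Heat map of posterior node-by-position frequencies."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        p = len(self.labels)
        im = ax.imshow(self.posterior.position_matrix, cmap="Blues", vmin=0, vmax=1)
        ax.set_xticks(range(p), [str(t + 1) for t in range(p)])
        ax.set_yticks(range(p), self.labels)
        ax.set_xlabel("position in causal ordering")
        ax.set_ylabel("gene")
        ax.figure.colorbar(im, ax=ax, label="posterior frequency")
        return ax

    def save(self, out_dir) -> None:
        """Write effect matrices, position frequencies, chain log-likelihoods
        and a JSON manifest into a directory."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.total_effects.to_csv(out / "effects_total.csv")
        self.direct_effects.to_csv(out / "effects_direct.csv")
        self.position_frequencies.to_csv(out / "position_matrix.csv")
        pd.DataFrame({"loglik": self.posterior.logliks}).to_csv(
            out / "chain_logliks.csv", index=False
        )
        manifest = {
            "mode": self.config.mode,
            "n_iter": self.config.n_iter,
            "burn_in": self.config.burn_in,
            "thin": self.config.thin,
            "seed": self.config.seed,
            "eta_used": self.posterior.eta_used,
            "acceptance_rate": self.posterior.acceptance_rate,
            "best_loglik": self.loglik,
            "best_ordering": self.ordering,
            "estimator": self.estimator,
            "degenerate_edges": sorted(self.posterior.best_fit.degenerate_edges),
            "undefined_genes": self.posterior.best_fit.undefined_genes,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
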