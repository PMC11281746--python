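"""Posterior sample containers shared by all Bayesian fitters."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PosteriorSummary:
    """Posterior draws plus per-parameter summaries and deviance bookkeeping.

    ``samples`` is (draws x parameters) in the order of ``names``;
    ``deviance_samples`` holds the model deviance evaluated at each draw and
    ``deviance_at_mean`` the deviance at the posterior mean, the two inputs of
    the DIC.  ``diagnostics`` carries convergence information (e.g. split
    R-hat per monitored parameter and a ``converged`` flag).
    """

    names: list[str]
    samples: np.ndarray
    deviance_samples: np.ndarray
    deviance_at_mean: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.names):
            raise ValueError("samples must be (draws, len(names))")

    @property
    def n_draws(self) -> int:
        return self.samples.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.samples[:, self.names.index(name)]

    def mean(self, name: str) -> float:
        return float(self.column(name).mean())

    def summary(self) -> pd.DataFrame:
        """Per-parameter mean, sd and 2.5/50/97.5% quantiles."""
        q = np.quantile(self.samples, [0.025, 0.5, 0.975], axis=0)
        return pd.DataFrame(
            {
                "parameter": self.names,
                "mean": self.samples.mean(axis=0),
                "sd": self.samples.std(axis=0, ddof=1),
                "q2.5": q[0],
                "q50": q[1],
                "q97.5": q[2],
            }
        )

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1 - level) / 2
        col = self.column(name)
        return float(np.quantile(col, a)), float(np.quantile(col, 1 - a))


def split_rhat(chains: np.ndarray) -> float:
    """Split-half Gelman-Rubin potential scale reduction for one parameter.

    ``chains`` is (n_chains, n_draws); each chain is split in half, giving
    2*n_chains sequences whose between/within variance ratio is returned.
    """
    chains = np.asarray(chains, dtype=float)
    n = chains.shape[1] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m = halves.shape[0]
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0 if between == 0 else np.inf
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))
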