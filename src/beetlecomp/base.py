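"""Shared Results machinery for the three experiment models.

Each model's ``fit()`` returns a subclass of :class:`PosteriorResults`, which
stores aligned posterior draws per group for one or more derived traits,
exposes credible intervals, a ``summary()`` table, MCMC diagnostics and a
forest-style interval plot.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import TraitPosterior

__all__ = ["PosteriorResults"]


class PosteriorResults:
    """Posterior draws of group-level traits plus sampler diagnostics.

    Parameters
    ----------
    groups : list of str
        Groups actually fitted (skipped groups are absent).
    draws : dict of str -> ndarray
        Trait name -> (n_draws, n_groups) matrix; draws are aligned across
        traits and groups (same MCMC iteration index).
    diagnostics : pandas.DataFrame
        Per-group max split-R-hat and min bulk ESS over model parameters.
    warnings : list of str
    n_obs : pandas.DataFrame or None
        Per-group observation counts.
    """

    def __init__(self, groups, draws, diagnostics=None, warnings=(), n_obs=None):
        self.groups = list(groups)
        self.draws = {k: np.asarray(v, dtype=float) for k, v in draws.items()}
        for k, v in self.draws.items():
            if v.shape[1] != len(self.groups):
                raise ValueError(f"draws for {k} do not match group count")
        self.diagnostics = diagnostics
        self.warnings = list(warnings)
        self.n_obs = n_obs

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def trait_posterior(self, name: str) -> TraitPosterior:
        """Extract one trait as a :class:`TraitPosterior` for correlation stages."""
        return TraitPosterior(name, self.draws[name], list(self.groups))

    def mean(self, name: str) -> pd.Series:
        return pd.Series(self.draws[name].mean(axis=0), index=self.groups, name=name)

    def ci(self, name: str, level: float = 0.95) -> pd.DataFrame:
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        a = (1 - level) / 2
        lo, hi = np.quantile(self.draws[name], [a, 1 - a], axis=0)
        return pd.DataFrame({"low": lo, "high": hi}, index=self.groups)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior mean, sd and equal-tailed interval per trait per group."""
        cols = {}
        for name, d in self.draws.items():
            a = (1 - level) / 2
            lo, hi = np.quantile(d, [a, 1 - a], axis=0)
            cols[f"{name}_mean"] = d.mean(axis=0)
            cols[f"{name}_sd"] = d.std(axis=0, ddof=1)
            cols[f"{name}_low"] = lo
            cols[f"{name}_high"] = hi
        out = pd.DataFrame(cols, index=pd.Index(self.groups, name="group"))
        if self.diagnostics is not None:
            out = out.join(self.diagnostics)
        return out

    def plot_intervals(self, name: str, level: float = 0.95, ax=None, ref=None):
        """Forest plot of posterior means with credible intervals."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.35 * len(self.groups) + 1))
        m = self.mean(name)
        ci = self.ci(name, level)
        y = np.arange(len(self.groups))
        ax.errorbar(
            m.values, y,
            xerr=[m.values - ci["low"].values, ci["high"].values - m.values],
            fmt="o", color="k", ecolor="gray", capsize=2,
        )
        if ref is not None:
            ax.axvline(ref, ls="--", color="gray", lw=0.8)
        ax.set_yticks(y)
        ax.set_yticklabels(self.groups)
        ax.set_xlabel(name)
        return ax

    def __repr__(self) -> str:
        return (
            f"<{type(self).__name__}: {len(self.groups)} groups, "
            f"{self.n_draws} draws, traits {sorted(self.draws)}>"
        )
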