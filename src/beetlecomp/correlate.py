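"""Posterior-propagated trait correlations and candidate linear models.

Because every group-level trait is estimated with uncertainty, a single
plug-in correlation of posterior means would pretend the traits were measured
exactly.  Instead, each MCMC draw of the joint posterior supplies one vector
of trait values per group, hence one Pearson correlation per draw; collecting
them yields a posterior distribution of the correlation coefficient whose 95%
credible interval carries the propagated uncertainty.

Two variants per trait pair:

* ``raw`` — centered Pearson correlation of the group values;
* ``pic`` — phylogenetically independent contrasts are computed for each
  draw and correlated *through the origin* (contrasts have expectation zero
  and arbitrary sign, so the no-intercept convention is the standard one).

The canonical pairings: (|L|, delta) — bias in either direction against the
inbreeding effect — and (L, log h) — signed bias against polygyny.

Separately, five candidate Gaussian linear models for mean sex bias
(null; delta; log h; additive; interaction) are compared by maximum
likelihood, AIC weights and likelihood-ratio tests against the null.  This
stage uses posterior means only and ignores phylogeny (there is no
group-level replication to separate phylogenetic effects from residual
variance), so a caution is attached to its output.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import Phylogeny, TraitPosterior
from .phylo import contrast_matrix

__all__ = [
    "pearson_origin",
    "CorrelationPosterior",
    "posterior_correlation",
    "fit_candidate_lms",
    "CANDIDATE_MODELS",
]


def pearson_origin(x, y) -> float:
    """Through-origin correlation sum(xy) / sqrt(sum(x^2) sum(y^2)).

    NaN (flagged missing) when either vector is identically zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    sx = np.sum(x * x)
    sy = np.sum(y * y)
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.sum(x * y) / np.sqrt(sx * sy))


@dataclass
class CorrelationPosterior:
    """Posterior draws of one trait-pair correlation."""

    pair: tuple
    variant: str  # "raw" or "pic"
    r_draws: np.ndarray
    groups: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r_draws = np.asarray(self.r_draws, dtype=float)
        if np.any(np.abs(self.r_draws) > 1 + 1e-9):
            raise ValueError("correlation draws outside [-1, 1]")

    @property
    def ci_95(self) -> tuple:
        lo, hi = np.quantile(self.r_draws, [0.025, 0.975])
        return (float(lo), float(hi))

    @property
    def significant(self) -> bool:
        lo, hi = self.ci_95
        return not (lo <= 0.0 <= hi)

    @property
    def mean(self) -> float:
        return float(self.r_draws.mean())

    def summary(self) -> pd.Series:
        lo, hi = self.ci_95
        return pd.Series(
            {
                "pair": f"{self.pair[0]}~{self.pair[1]}",
                "variant": self.variant,
                "mean_r": self.mean,
                "ci_low": lo,
                "ci_high": hi,
                "significant": self.significant,
                "n_groups": len(self.groups),
            }
        )


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = np.sum(a * b, axis=1)
    den = np.sqrt(np.sum(a * a, axis=1) * np.sum(b * b, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _rowwise_origin(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    num = np.sum(a * b, axis=1)
    den = np.sqrt(np.sum(a * a, axis=1) * np.sum(b * b, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def posterior_correlation(
    trait_a: TraitPosterior,
    trait_b: TraitPosterior,
    variant: str = "raw",
    tree: Phylogeny | None = None,
    center_pics: bool = False,
) -> CorrelationPosterior:
    """Correlation posterior for a pair of trait posteriors.

    Groups are aligned pairwise (a group missing either trait is dropped);
    draws must already be aligned (same count, same iteration indexing).  For
    ``variant="pic"`` the tree is pruned to the shared groups and contrasts
    are recomputed for every posterior draw via the tree's contrast operator.
    """
    if variant not in ("raw", "pic"):
        raise ValueError("variant must be 'raw' or 'pic'")
    a, b = trait_a.align_with(trait_b)
    if len(a.groups) < 3:
        raise ValueError(
            f"only {len(a.groups)} shared groups — too few for a correlation"
        )
    if variant == "raw":
        r = _rowwise_pearson(a.draws, b.draws)
    else:
        if tree is None:
            raise ValueError("variant='pic' requires a tree")
        sub = tree if set(tree.tip_labels) == set(a.groups) else tree.prune_to(a.groups)
        A, _, _ = contrast_matrix(sub, a.groups)
        ca = a.draws @ A.T
        cb = b.draws @ A.T
        if center_pics:
            r = _rowwise_pearson(ca, cb)
        else:
            r = _rowwise_origin(ca, cb)
    if np.isnan(r).any():
        _warnings.warn("degenerate draws produced undefined correlations; dropped")
        r = r[~np.isnan(r)]
        if r.size == 0:
            raise ValueError("all correlation draws undefined")
    return CorrelationPosterior(
        (trait_a.trait_name, trait_b.trait_name), variant, r, list(a.groups)
    )


#: name -> predictor columns for the five candidate mean-bias models
CANDIDATE_MODELS = {
    "null": [],
    "inbreeding": ["delta"],
    "polygyny": ["log_h"],
    "additive": ["delta", "log_h"],
    "interaction": ["delta", "log_h", "delta:log_h"],
}


def fit_candidate_lms(
    trait_means: pd.DataFrame, response: str = "L"
) -> pd.DataFrame:
    """AIC/LRT comparison of the five candidate linear models.

    ``trait_means``: one row per group with columns for the response (mean
    sex bias, ``L`` by default) and the predictors ``delta`` and ``log_h``.
    Complete cases only, so the five AICs are computed on identical data.
    Parameters are counted including the residual variance
    (k = 2, 3, 3, 4, 5); AIC = 2k - 2 logL; weights are the normalized
    relative likelihoods; the LRT compares each model to the null with a
    chi-squared reference on the parameter-count difference.
    """
    need = [response, "delta", "log_h"]
    missing = [c for c in need if c not in trait_means.columns]
    if missing:
        raise ValueError(f"trait_means lacks columns {missing}")
    df = trait_means[need].dropna()
    n = len(df)
    _warnings.warn(
        "candidate linear models use group means and ignore phylogeny; "
        "interpret with caution"
    )
    y = df[response].to_numpy()
    rows = []
    ll_null = None
    for name, preds in CANDIDATE_MODELS.items():
        cols = [np.ones(n)]
        for p in preds:
            if ":" in p:
                p1, p2 = p.split(":")
                cols.append((df[p1] * df[p2]).to_numpy())
            else:
                cols.append(df[p].to_numpy())
        X = np.column_stack(cols)
        k = X.shape[1] + 1  # + residual variance
        if n < k:
            rows.append(
                {"model": name, "k": k, "loglik": np.nan, "aic": np.nan,
                 "unfit": True}
            )
            continue
        fit = sm.OLS(y, X).fit()
        ll = float(fit.llf)  # Gaussian ML log-likelihood (variance MLE n-denominator)
        if name == "null":
            ll_null = ll
        rows.append(
            {"model": name, "k": k, "loglik": ll, "aic": 2 * k - 2 * ll,
             "unfit": False}
        )
    out = pd.DataFrame(rows).set_index("model")
    ok = ~out["unfit"]
    d = out.loc[ok, "aic"] - out.loc[ok, "aic"].min()
    w = np.exp(-d / 2)
    out.loc[ok, "aic_weight"] = w / w.sum()
    for name in out.index:
        if name == "null" or out.loc[name, "unfit"] or ll_null is None:
            out.loc[name, "lrt_p"] = np.nan
            continue
        lr = 2 * (out.loc[name, "loglik"] - ll_null)
        dk = out.loc[name, "k"] - out.loc["null", "k"]
        out.loc[name, "lrt_p"] = float(stats.chi2.sf(max(lr, 0.0), dk))
    out["n"] = n
    return out.drop(columns=["unfit"])
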