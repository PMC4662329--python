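"""Synthetic study generator.

Emulates the three laboratory experiments on a clade of bean-beetle groups:

* a 16-tip phylogeny (Yule simulation, or a shipped *synthetic* fixture tree
  whose tips carry the real groups' four-letter abbreviations but whose
  topology and branch lengths are plausible inventions, not estimates);
* group-level true traits — log dispersal sex-ratio ``L``, proportional
  inbreeding effect ``delta`` and log harem size ``log_h`` — evolved along the
  tree by (optionally correlated) Brownian motion;
* the three observation tables, each drawn from exactly the sampling
  distribution the corresponding fitting module assumes, so posterior means
  are consistent estimators and every stage has a parameter-recovery test.

Defaults mirror the study design: 6 release trials of 5 beetles per sex on a
41-patch linear array; 3 blocks of 2 maternal families with 4 crosses each;
a {1,5,9} x {1,5,9} female-by-male response surface with 2 replicates.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .io import Phylogeny
from .mating import recruitment_mean

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_traits",
    "simulate_dispersal",
    "simulate_inbreeding",
    "simulate_mating",
    "simulate_study",
    "fixture_tree",
]

_TRAITS = ("L", "delta", "log_h")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic comparative study.

    Trait roots and Brownian-motion rates are chosen to reproduce the spread
    observed across real bean-beetle groups: mostly male-biased dispersal
    around exp(L) ~ 0.75, weak inbreeding effects of either sign, and strong
    polygyny (harem sizes ~ 3-30, with occasional extreme tips).
    """

    n_groups: int = 16
    tree_model: str = "yule"  # or "fixture" (16-tip shipped tree)
    trait_root_values: tuple = (-0.3, -0.05, 2.3)  # (L, delta, log_h)
    trait_bm_rates: tuple = (0.2, 0.05, 1.0)  # variance per unit branch length
    trait_correlations: tuple = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )
    # dispersal experiment
    n_trials: int = 6
    per_sex_per_trial: int = 5
    n_patches: int = 41
    mortality_prob: float = 0.05
    mu_M: float = 4.0  # baseline male mean displacement, patches
    # inbreeding experiment
    n_blocks: int = 3
    families_per_block: int = 2
    baseline_log_mean: float = float(np.log(55.0))
    sigma_block: float = 0.2
    sigma_family: float = 0.2
    inbreeding_groups_excluded: tuple = ()  # e.g. ("CAPH",)
    # mating experiment
    mating_grid: tuple = ((1, 1), (1, 5), (1, 9), (5, 1), (5, 5), (5, 9), (9, 1), (9, 5), (9, 9))
    mating_replicates: int = 2
    mating_lambda: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 3:
            raise ValueError("n_groups must be >= 3")
        if self.n_patches % 2 == 0:
            raise ValueError("n_patches must be odd (central release patch)")
        if any(r < 0 for r in self.trait_bm_rates):
            raise ValueError("Brownian-motion rates must be >= 0")
        if not 0 <= self.mortality_prob < 1:
            raise ValueError("mortality_prob must be in [0, 1)")
        R = np.asarray(self.trait_correlations, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R, R.T):
            raise ValueError("trait_correlations must be a symmetric 3x3 matrix")
        if np.linalg.eigvalsh(R).min() < -1e-9:
            raise ValueError("trait_correlations must be positive semi-definite")

    @property
    def max_distance(self) -> int:
        return (self.n_patches - 1) // 2

    def trait_increment_cov(self) -> np.ndarray:
        """Covariance of the 3-trait BM increment per unit branch length."""
        d = np.sqrt(np.asarray(self.trait_bm_rates, dtype=float))
        R = np.asarray(self.trait_correlations, dtype=float)
        return d[:, None] * R * d[None, :]

    # -- (de)serialisation for the CLI --------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["trait_root_values"] = list(self.trait_root_values)
        d["trait_bm_rates"] = list(self.trait_bm_rates)
        d["trait_correlations"] = [list(r) for r in self.trait_correlations]
        d["mating_grid"] = [list(c) for c in self.mating_grid]
        d["inbreeding_groups_excluded"] = list(self.inbreeding_groups_excluded)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("trait_root_values", "trait_bm_rates"):
            if key in d:
                d[key] = tuple(d[key])
        if "trait_correlations" in d:
            d["trait_correlations"] = tuple(tuple(r) for r in d["trait_correlations"])
        if "mating_grid" in d:
            d["mating_grid"] = tuple(tuple(c) for c in d["mating_grid"])
        if "inbreeding_groups_excluded" in d:
            d["inbreeding_groups_excluded"] = tuple(d["inbreeding_groups_excluded"])
        return cls(**d)


def _substreams(seed: int, n: int = 5) -> list[np.random.Generator]:
    """Fixed-offset substreams: one per pipeline stage, all from the master seed."""
    return [np.random.default_rng(ss) for ss in np.random.SeedSequence(seed).spawn(n)]


def fixture_tree() -> Phylogeny:
    """The shipped synthetic 16-tip tree with real group abbreviations.

    Topology and branch lengths are hand-written plausible values, not the
    published consensus tree (whose branch lengths are not available in
    machine-readable form).
    """
    text = (
        resources.files("beetlecomp").joinpath("data/bruchinae_16tip.nwk").read_text()
    )
    return Phylogeny.from_newick(text)


def simulate_tree(config: SimulationConfig) -> Phylogeny:
    """A rooted binary ultrametric tree for the synthetic study.

    Pure-birth (Yule) simulation via dendropy, rescaled to unit root depth so
    Brownian-motion rates have a fixed meaning across replicates.  Tips are
    labelled ``G01..Gnn`` (or the real abbreviations for the fixture tree).
    """
    if config.tree_model == "fixture":
        tree = fixture_tree()
        if config.n_groups != tree.n_tips:
            raise ValueError("fixture tree has 16 tips; set n_groups=16")
        return tree
    if config.tree_model != "yule":
        raise ValueError(f"unknown tree_model {config.tree_model!r}")
    seed_int = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))
    py_rng = random.Random(seed_int)
    t = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=config.n_groups,
        rng=py_rng,
    )
    # the process stops exactly at the n-th birth, leaving zero-length pendant
    # edges; run the clock on to the next would-be speciation so every branch
    # is strictly positive and the tree stays ultrametric
    extra = py_rng.expovariate(config.n_groups * 1.0)
    for leaf in t.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    depth = max(lf.distance_from_root() for lf in t.leaf_node_iter())
    for node in t.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length /= depth
    for i, leaf in enumerate(t.leaf_node_iter()):
        leaf.taxon.label = f"G{i + 1:02d}"
    return Phylogeny(t)


def simulate_traits(
    tree: Phylogeny, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Evolve (L, delta, log_h) along the tree by correlated Brownian motion.

    The increment over a branch of length ``t`` is multivariate normal with
    covariance ``t * D R D`` where ``D = diag(sqrt(rates))`` and ``R`` the
    increment correlation matrix; the root sits at ``trait_root_values``.
    """
    if rng is None:
        rng = _substreams(config.seed)[1]
    cov = config.trait_increment_cov()
    # PSD by construction (validated in config); eigen-root handles rank deficiency
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    A = V * np.sqrt(w)  # A @ A.T == cov
    values: dict[int, np.ndarray] = {}
    root = tree.tree.seed_node
    values[id(root)] = np.asarray(config.trait_root_values, dtype=float)
    rows = {}
    for node in tree.tree.preorder_node_iter():
        if node is root:
            pass
        else:
            parent_val = values[id(node.parent_node)]
            t_len = node.edge.length
            incr = A @ rng.standard_normal(3) * np.sqrt(t_len)
            values[id(node)] = parent_val + incr
        if node.is_leaf():
            rows[node.taxon.label] = values[id(node)]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(_TRAITS))
    df.index.name = "group"
    return df.loc[sorted(df.index)]


def _truncated_poisson(
    rng: np.random.Generator, mu: float, size: int, max_value: int
) -> np.ndarray:
    """Poisson draws truncated at `max_value` by resampling."""
    tail = stats.poisson.sf(max_value, mu)
    if tail > 0.01:
        warnings.warn(
            f"Poisson(mu={mu:.3g}) has {tail:.3f} probability beyond the array "
            f"edge ({max_value} patches); the plain-Poisson fit will be "
            "boundary-biased",
            stacklevel=3,
        )
    out = rng.poisson(mu, size)
    bad = out > max_value
    while bad.any():
        out[bad] = rng.poisson(mu, int(bad.sum()))
        bad = out > max_value
    return out


def simulate_dispersal(
    true_traits: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Dispersal-trial table: per-beetle Poisson displacement, sex means
    ``mu_M`` and ``mu_F = mu_M * exp(L)``, truncated at the array edge;
    per-beetle mortality thins the observed distances."""
    if rng is None:
        rng = _substreams(config.seed)[2]
    mu_M = config.mu_M
    if mu_M <= 0:
        raise ValueError("mu_M must be positive")
    rows = []
    per_trial = config.per_sex_per_trial
    for group, L in true_traits["L"].items():
        mus = {"F": mu_M * float(np.exp(L)), "M": mu_M}
        for trial in range(1, config.n_trials + 1):
            for sex in ("F", "M"):
                dist = _truncated_poisson(rng, mus[sex], per_trial, config.max_distance)
                died = rng.random(per_trial) < config.mortality_prob
                for d, dd in zip(dist, died):
                    rows.append(
                        {
                            "group": group,
                            "trial_id": f"{group}-t{trial}",
                            "sex": sex,
                            "distance": pd.NA if dd else int(d),
                            "died": int(dd),
                        }
                    )
    df = pd.DataFrame(rows)
    df["distance"] = df["distance"].astype("Int64")
    df["died"] = df["died"].astype(bool)
    return df


def simulate_inbreeding(
    true_traits: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cross table: 3 blocks x (2 outbred + 2 inbred) crosses per group.

    Counts are Poisson with log-mean ``beta0 + b_block + f_maternal +
    1{inbred} * log(1 + delta)``, so the inbred/outbred mean ratio equals
    ``1 + delta`` conditionally on the random effects.
    """
    if rng is None:
        rng = _substreams(config.seed)[3]
    if (true_traits["delta"] <= -1).any():
        raise ValueError("delta must exceed -1 (multiplicative effect)")
    rows = []
    for group, delta in true_traits["delta"].items():
        if group in config.inbreeding_groups_excluded:
            continue
        for b in range(1, config.n_blocks + 1):
            block = f"{group}-b{b}"
            b_eff = rng.normal(0.0, config.sigma_block)
            fams = [f"{block}-f{j}" for j in range(1, config.families_per_block + 1)]
            f_eff = rng.normal(0.0, config.sigma_family, len(fams))
            # canonical block: 2 outbred (AxB, BxA) + 2 inbred (AxA, BxB)
            crosses = [
                (fams[0], fams[1], "outbred"),
                (fams[1], fams[0], "outbred"),
                (fams[0], fams[0], "inbred"),
                (fams[1], fams[1], "inbred"),
            ]
            for mat, pat, ctype in crosses:
                eta = (
                    config.baseline_log_mean
                    + b_eff
                    + f_eff[fams.index(mat)]
                    + (np.log1p(delta) if ctype == "inbred" else 0.0)
                )
                rows.append(
                    {
                        "group": group,
                        "block": block,
                        "maternal_family": mat,
                        "paternal_family": pat,
                        "cross_type": ctype,
                        "offspring_count": int(rng.poisson(np.exp(eta))),
                    }
                )
    return pd.DataFrame(rows)


def simulate_mating(
    true_traits: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Response-surface table: recruits ~ Poisson(harmonic-mean model mean)."""
    if rng is None:
        rng = _substreams(config.seed)[4]
    lam = config.mating_lambda
    if lam <= 0:
        raise ValueError("mating_lambda must be positive")
    rows = []
    for group, log_h in true_traits["log_h"].items():
        h = float(np.exp(log_h))
        rep = 0
        for F, M in config.mating_grid:
            for _ in range(config.mating_replicates):
                rep += 1
                mean = recruitment_mean(F, M, lam, h)
                rows.append(
                    {
                        "group": group,
                        "replicate": f"{group}-r{rep}",
                        "females_0": int(F),
                        "males_0": int(M),
                        "recruits_1": int(rng.poisson(mean)),
                    }
                )
    return pd.DataFrame(rows)


def simulate_study(config: SimulationConfig) -> dict:
    """Full synthetic study: tree, true traits and the three tables.

    Each stage draws from its own substream of the master seed, so identical
    configs give byte-identical tables.
    """
    streams = _substreams(config.seed)
    tree = simulate_tree(config)
    traits = simulate_traits(tree, config, streams[1])
    return {
        "tree": tree,
        "true_traits": traits,
        "dispersal": simulate_dispersal(traits, config, streams[2]),
        "crosses": simulate_inbreeding(traits, config, streams[3]),
        "mating": simulate_mating(traits, config, streams[4]),
    }
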