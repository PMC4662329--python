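"""Data model, validation and readers/writers.

Four kinds of input move through the pipeline:

* a rooted (or rootable) phylogeny in Newick with tips labelled by beetle-group
  abbreviation (:class:`Phylogeny`, backed by :mod:`dendropy`);
* three tidy CSV observation tables — dispersal trials, inbreeding crosses and
  mating response-surface counts — validated row-by-row against the schemas
  below;
* posterior trait draws in long CSV format with a JSON manifest.

Validation is deliberately strict: sex codes other than ``F``/``M``, a distance
recorded for a beetle that died, or an outbred cross between identical maternal
and paternal families are all rejected with row-numbered messages rather than
silently recoded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "Phylogeny",
    "read_newick",
    "read_dispersal",
    "read_crosses",
    "read_mating",
    "TraitPosterior",
    "write_posteriors",
    "read_posteriors",
    "DISPERSAL_COLUMNS",
    "CROSS_COLUMNS",
    "MATING_COLUMNS",
]

DISPERSAL_COLUMNS = ["group", "trial_id", "sex", "distance", "died"]
CROSS_COLUMNS = [
    "group",
    "block",
    "maternal_family",
    "paternal_family",
    "cross_type",
    "offspring_count",
]
MATING_COLUMNS = ["group", "replicate", "females_0", "males_0", "recruits_1"]


class SchemaError(ValueError):
    """A table or tree violated its schema."""


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted-or-rootable tree with branch lengths, tips = beetle groups.

    Thin wrapper over :class:`dendropy.Tree` adding the validation this
    pipeline needs (unique tip labels, branch lengths present and
    non-negative, binary after rooting) and convenience accessors.
    """

    def __init__(self, tree: dendropy.Tree, validate: bool = True):
        self.tree = tree
        if validate:
            self.validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, validate: bool = True) -> "Phylogeny":
        s = newick.strip()
        if not s.endswith(";"):  # tolerate the no-semicolon dialect
            s += ";"
        try:
            tree = dendropy.Tree.get(
                data=s, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parser classes
            raise SchemaError(f"malformed Newick: {exc}") from exc
        return cls(tree, validate=validate)

    @classmethod
    def read(cls, path: str | Path, validate: bool = True) -> "Phylogeny":
        return cls.from_newick(Path(path).read_text(), validate=validate)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise SchemaError(f"duplicate tip labels: {dup}")
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            if node.edge.length is None:
                raise SchemaError(
                    f"missing branch length on edge above "
                    f"{node.taxon.label if node.taxon else 'internal node'}"
                )
            if node.edge.length < 0:
                raise SchemaError("negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def is_binary(self) -> bool:
        """True if every internal node (incl. the root) has exactly 2 children."""
        for node in self.tree.preorder_internal_node_iter():
            if len(node.child_nodes()) != 2:
                return False
        return True

    def check_binary(self, resolve_polytomies: bool = False) -> "Phylogeny":
        """Raise on polytomies, or resolve them to zero-length branches."""
        if self.is_binary():
            return self
        if not resolve_polytomies:
            raise SchemaError(
                "tree contains polytomies; pass resolve_polytomies=True to "
                "resolve them with zero-length branches"
            )
        t = self.copy().tree
        t.resolve_polytomies(rng=None)
        for node in t.preorder_node_iter():
            if node is not t.seed_node and node.edge.length is None:
                node.edge.length = 0.0
        return Phylogeny(t)

    # -- manipulation -------------------------------------------------------

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1), validate=False)

    def prune_to(self, labels) -> "Phylogeny":
        """Subtree induced by `labels` (suppressing unifurcations)."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise SchemaError(f"tips not in tree: {sorted(missing)}")
        t = self.tree.clone(depth=1)
        taxa = [lf.taxon for lf in t.leaf_node_iter() if lf.taxon.label in keep]
        t.retain_taxa(taxa)
        return Phylogeny(t)

    # -- output -------------------------------------------------------------

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.newick() + "\n")


def read_newick(path: str | Path) -> Phylogeny:
    """Parse a Newick file into a validated :class:`Phylogeny`."""
    return Phylogeny.read(path)


# ---------------------------------------------------------------------------
# observation tables
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def _check_groups(df: pd.DataFrame, groups, what: str) -> None:
    if groups is None:
        return
    bad = sorted(set(df["group"]) - set(groups))
    if bad:
        raise SchemaError(f"{what}: unknown group labels {bad}")


def read_dispersal(
    path_or_df, groups=None, n_patches: int | None = None
) -> pd.DataFrame:
    """Read and validate dispersal-trial records.

    Columns: group, trial_id, sex (F/M), distance (absolute patches moved,
    empty when the beetle died), died (0/1).  ``distance`` must be present
    exactly when ``died`` is false, and — when the array geometry is given —
    cannot exceed ``(n_patches - 1) / 2``.
    """
    df = _as_df(path_or_df)
    _require_columns(df, DISPERSAL_COLUMNS, "dispersal table")
    df = df[DISPERSAL_COLUMNS].copy()
    _check_groups(df, groups, "dispersal table")

    bad_sex = ~df["sex"].isin(["F", "M"])
    if bad_sex.any():
        rows = _rows(bad_sex)
        raise SchemaError(f"dispersal table: sex must be 'F' or 'M' (rows {rows})")

    df["died"] = _as_bool(df["died"], "dispersal table", "died")
    dist = pd.to_numeric(df["distance"], errors="coerce")

    alive = ~df["died"]
    missing_alive = alive & dist.isna()
    if missing_alive.any():
        raise SchemaError(
            f"dispersal table: surviving beetles need a distance "
            f"(rows {_rows(missing_alive)})"
        )
    present_dead = df["died"] & df["distance"].notna() & (df["distance"].astype(str).str.strip() != "")
    if present_dead.any():
        raise SchemaError(
            f"dispersal table: dead beetles must have empty distance "
            f"(rows {_rows(present_dead)})"
        )
    noninteger = alive & ((dist % 1 != 0) | (dist < 0))
    if noninteger.any():
        raise SchemaError(
            f"dispersal table: distance must be a non-negative integer "
            f"(rows {_rows(noninteger)})"
        )
    if n_patches is not None:
        lim = (n_patches - 1) // 2
        over = alive & (dist > lim)
        if over.any():
            raise SchemaError(
                f"dispersal table: distance exceeds array half-length {lim} "
                f"(rows {_rows(over)})"
            )
    df["distance"] = dist.astype("Int64")
    return df


def read_crosses(path_or_df, groups=None) -> pd.DataFrame:
    """Read and validate inbreeding-cross records.

    ``cross_type`` must equal ``inbred`` exactly when maternal and paternal
    family coincide.
    """
    df = _as_df(path_or_df)
    _require_columns(df, CROSS_COLUMNS, "cross table")
    df = df[CROSS_COLUMNS].copy()
    _check_groups(df, groups, "cross table")

    bad_type = ~df["cross_type"].isin(["inbred", "outbred"])
    if bad_type.any():
        raise SchemaError(
            f"cross table: cross_type must be inbred/outbred (rows {_rows(bad_type)})"
        )
    same = df["maternal_family"].astype(str) == df["paternal_family"].astype(str)
    mism = (df["cross_type"] == "inbred") != same
    if mism.any():
        raise SchemaError(
            f"cross table: cross_type inconsistent with family labels "
            f"(rows {_rows(mism)})"
        )
    counts = pd.to_numeric(df["offspring_count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts % 1 != 0)
    if bad.any():
        raise SchemaError(
            f"cross table: offspring_count must be a non-negative integer "
            f"(rows {_rows(bad)})"
        )
    df["offspring_count"] = counts.astype(int)
    return df


def read_mating(path_or_df, groups=None) -> pd.DataFrame:
    """Read and validate mating response-surface records."""
    df = _as_df(path_or_df)
    _require_columns(df, MATING_COLUMNS, "mating table")
    df = df[MATING_COLUMNS].copy()
    _check_groups(df, groups, "mating table")
    for col, lo in [("females_0", 1), ("males_0", 1), ("recruits_1", 0)]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < lo) | (vals % 1 != 0)
        if bad.any():
            raise SchemaError(
                f"mating table: {col} must be an integer >= {lo} (rows {_rows(bad)})"
            )
        df[col] = vals.astype(int)
    return df


def _as_df(path_or_df) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        return path_or_df.copy()
    return pd.read_csv(path_or_df, dtype=str).rename(columns=str.strip)


def _as_bool(col: pd.Series, what: str, name: str) -> pd.Series:
    mapping = {
        "0": False, "1": True, "false": False, "true": True,
        False: False, True: True, 0: False, 1: True,
    }
    out = col.map(lambda v: mapping.get(str(v).strip().lower(), None))
    if out.isna().any():
        raise SchemaError(f"{what}: {name} must be boolean (0/1/true/false)")
    return out.astype(bool)


def _rows(mask: pd.Series) -> list[int]:
    return [int(i) for i in mask[mask].index[:10]]


# ---------------------------------------------------------------------------
# trait posteriors
# ---------------------------------------------------------------------------

TRAIT_NAMES = ("L", "abs_L", "delta", "log_h", "lambda", "h", "mu_F", "mu_M")


@dataclass
class TraitPosterior:
    """Posterior draws of one group-level trait.

    ``draws`` has shape (n_draws, n_groups); column order follows ``groups``.
    Groups for which the trait was never measured are absent, not NaN.
    """

    trait_name: str
    draws: np.ndarray
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2:
            raise ValueError("draws must be 2-d (n_draws, n_groups)")
        if self.draws.shape[0] == 0 or self.draws.shape[1] == 0:
            raise ValueError("empty posterior")
        if self.draws.shape[1] != len(self.groups):
            raise ValueError("draws/groups shape mismatch")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate group labels")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("non-finite posterior draws")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def mean(self) -> pd.Series:
        return pd.Series(self.draws.mean(axis=0), index=self.groups, name=self.trait_name)

    def ci(self, level: float = 0.95) -> pd.DataFrame:
        a = (1 - level) / 2
        lo, hi = np.quantile(self.draws, [a, 1 - a], axis=0)
        return pd.DataFrame({"low": lo, "high": hi}, index=self.groups)

    def subset(self, groups) -> "TraitPosterior":
        idx = [self.groups.index(g) for g in groups]
        return TraitPosterior(self.trait_name, self.draws[:, idx], list(groups))

    def align_with(self, other: "TraitPosterior"):
        """Restrict both posteriors to their shared groups, in sorted order."""
        common = sorted(set(self.groups) & set(other.groups))
        if not common:
            raise ValueError(
                f"no shared groups between {self.trait_name} and {other.trait_name}"
            )
        if self.n_draws != other.n_draws:
            raise ValueError(
                f"draw-count mismatch: {self.n_draws} vs {other.n_draws}"
            )
        return self.subset(common), other.subset(common)


def write_posteriors(
    traits: dict[str, TraitPosterior], path: str | Path, seed: int | None = None
) -> None:
    """Write trait posteriors as long CSV (draw, group, trait, value) + manifest."""
    path = Path(path)
    frames = []
    n_draws = None
    for name, tp in traits.items():
        if n_draws is None:
            n_draws = tp.n_draws
        frames.append(
            pd.DataFrame(
                {
                    "draw": np.repeat(np.arange(tp.n_draws), len(tp.groups)),
                    "group": np.tile(tp.groups, tp.n_draws),
                    "trait": name,
                    "value": tp.draws.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    manifest = {
        "n_draws": {name: tp.n_draws for name, tp in traits.items()},
        "seed": seed,
        "format": "beetlecomp-posterior-v1",
    }
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=1)
    )


def read_posteriors(path: str | Path) -> dict[str, TraitPosterior]:
    """Read a long-format posterior CSV back; verifies the manifest if present."""
    path = Path(path)
    # round_trip parsing: stored draws must read back bit-identical
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["draw", "group", "trait", "value"], "posterior table")
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else None
    )
    out: dict[str, TraitPosterior] = {}
    for name, sub in df.groupby("trait", sort=False):
        wide = sub.pivot(index="draw", columns="group", values="value")
        if wide.isna().any().any():
            raise SchemaError(f"posterior table: missing draws for trait {name}")
        tp = TraitPosterior(str(name), wide.to_numpy(), [str(g) for g in wide.columns])
        if manifest is not None:
            expect = manifest["n_draws"].get(str(name))
            if expect is not None and expect != tp.n_draws:
                raise SchemaError(
                    f"posterior table: {name} has {tp.n_draws} draws, "
                    f"manifest says {expect}"
                )
        out[str(name)] = tp
    return out
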