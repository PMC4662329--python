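"""End-to-end orchestration: simulate -> fit x3 -> correlate/PIC -> model table.

One call runs the whole comparative study on synthetic data and leaves a
results directory with every intermediate artifact plus a manifest recording
the config hash, the master seed, per-file SHA-256 digests and convergence
summaries — identical inputs reproduce identical simulation tables bit for
bit and MC-equivalent posteriors.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings as _warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlate import fit_candidate_lms, posterior_correlation
from .dispersal import DispersalModel
from .inbreeding import InbreedingModel
from .io import write_posteriors
from .mating import MatingModel
from .mcmc import MCMCConfig
from .phylo import pic_diagnostic, pic, root_tree
from .simulate import SimulationConfig, simulate_study

__all__ = ["run_pipeline"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seeds(master: int, n: int = 4) -> list[int]:
    ss = np.random.SeedSequence(master).spawn(n)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss]


def run_pipeline(
    config: SimulationConfig,
    out_dir: str | Path,
    mcmc: MCMCConfig | None = None,
    verbose: bool = True,
) -> dict:
    """Run the full synthetic comparative study; returns the manifest."""
    t_start = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if mcmc is None:
        mcmc = MCMCConfig()
    seeds = _stage_seeds(config.seed)
    log = (lambda *a: print("[beetlecomp]", *a)) if verbose else (lambda *a: None)

    # --- stage 1: simulation ------------------------------------------------
    study = simulate_study(config)
    tree = study["tree"]
    files = {}
    tree.write(out / "tree.nwk")
    files["tree.nwk"] = _digest(out / "tree.nwk")
    for name, key in [
        ("true_traits.csv", "true_traits"),
        ("dispersal_trials.csv", "dispersal"),
        ("crosses.csv", "crosses"),
        ("mating.csv", "mating"),
    ]:
        df = study[key]
        df.to_csv(out / name, index=key == "true_traits")
        files[name] = _digest(out / name)
    log(f"simulated {config.n_groups} groups (seed {config.seed})")

    trait_groups = set(study["true_traits"].index)
    missing = trait_groups - set(tree.tip_labels)
    if missing:
        raise ValueError(f"groups absent from the tree: {sorted(missing)}")

    # --- stage 2: experiment fits ------------------------------------------
    conv = {}
    disp = DispersalModel(study["dispersal"], n_patches=config.n_patches).fit(
        MCMCConfig(chains=mcmc.chains, draws=mcmc.draws, warmup=mcmc.warmup,
                   seed=seeds[0])
    )
    inb = InbreedingModel(study["crosses"]).fit(
        MCMCConfig(chains=mcmc.chains, draws=mcmc.draws, warmup=mcmc.warmup,
                   seed=seeds[1])
    )
    mat = MatingModel(study["mating"]).fit(
        MCMCConfig(chains=mcmc.chains, draws=mcmc.draws, warmup=mcmc.warmup,
                   seed=seeds[2])
    )
    for stage, res in [("dispersal", disp), ("inbreeding", inb), ("mating", mat)]:
        conv[stage] = {
            "rhat_max": float(res.diagnostics["rhat_max"].max()),
            "ess_min": float(res.diagnostics["ess_min"].min()),
            "warnings": res.warnings,
        }
        for w in res.warnings:
            log(f"{stage}: {w}")
    write_posteriors(
        {"mu_F": disp.trait_posterior("mu_F"), "mu_M": disp.trait_posterior("mu_M"),
         "L": disp.trait_posterior("L"), "abs_L": disp.trait_posterior("abs_L")},
        out / "posterior_dispersal.csv", seed=seeds[0],
    )
    write_posteriors(
        {"delta": inb.trait_posterior("delta")},
        out / "posterior_inbreeding.csv", seed=seeds[1],
    )
    write_posteriors(
        {"lambda": mat.trait_posterior("lambda"), "h": mat.trait_posterior("h"),
         "log_h": mat.trait_posterior("log_h")},
        out / "posterior_mating.csv", seed=seeds[2],
    )
    for f in ("posterior_dispersal.csv", "posterior_inbreeding.csv",
              "posterior_mating.csv"):
        files[f] = _digest(out / f)
    log("fitted dispersal, inbreeding and mating models")

    # --- stage 3: correlations (raw + PIC) ---------------------------------
    rooted = tree if tree.is_binary() else root_tree(tree)
    diag = pic_diagnostic(pic(rooted, disp.mean("L"), "L"))
    pairs = [
        (disp.trait_posterior("abs_L"), inb.trait_posterior("delta")),
        (disp.trait_posterior("L"), mat.trait_posterior("log_h")),
    ]
    rows = []
    for a, b in pairs:
        for variant in ("raw", "pic"):
            cp = posterior_correlation(a, b, variant=variant, tree=rooted)
            rows.append(cp.summary())
    corr = pd.DataFrame(rows)
    corr.to_csv(out / "correlations.csv", index=False)
    files["correlations.csv"] = _digest(out / "correlations.csv")

    # --- stage 4: candidate linear models ----------------------------------
    means = pd.DataFrame(
        {"L": disp.mean("L"), "delta": inb.mean("delta"),
         "log_h": mat.mean("log_h")}
    )
    means.to_csv(out / "trait_means.csv")
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        aic = fit_candidate_lms(means)
    aic.to_csv(out / "aic_table.csv")
    files["trait_means.csv"] = _digest(out / "trait_means.csv")
    files["aic_table.csv"] = _digest(out / "aic_table.csv")
    log("correlations and model comparison written")

    manifest = {
        "version": __version__,
        "master_seed": config.seed,
        "stage_seeds": seeds[:3],
        "config_hash": hashlib.sha256(
            json.dumps(config.__dict__, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "mcmc": {"chains": mcmc.chains, "draws": mcmc.draws, "warmup": mcmc.warmup},
        "files": files,
        "convergence": conv,
        "pic_diagnostic": diag,
        "elapsed_s": round(time.time() - t_start, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    _write_report(out, disp, inb, mat, corr, aic, diag)
    log(f"done in {manifest['elapsed_s']} s -> {out}")
    return manifest


def _write_report(out, disp, inb, mat, corr, aic, diag) -> None:
    lines = ["beetlecomp study report", "=" * 23, ""]
    lines.append("Sex-bias classification (95% CI on L):")
    for g, c in disp.classify_bias().items():
        lines.append(f"  {g:>6}: {c}")
    lines.append("")
    lines.append("Inbreeding effect delta (95% CI excludes 0):")
    sig = inb.effect_significant()
    ci = inb.ci("delta")
    for g in inb.groups:
        lines.append(
            f"  {g:>6}: mean {inb.mean('delta')[g]:+.3f} "
            f"[{ci.loc[g, 'low']:+.3f}, {ci.loc[g, 'high']:+.3f}]"
            f"{'  *' if sig[g] else ''}"
        )
    lines.append("")
    lines.append("Harem size h (95% CI):")
    ci = mat.ci("h")
    for g in mat.groups:
        star = "  * polygynous" if mat.polygyny_significant()[g] else ""
        lines.append(
            f"  {g:>6}: mean {mat.mean('h')[g]:8.2f} "
            f"[{ci.loc[g, 'low']:.2f}, {ci.loc[g, 'high']:.2f}]{star}"
        )
    lines.append("")
    lines.append(f"PIC standardization diagnostic: {diag['verdict']} "
                 f"(slope p = {diag['p_value']:.3f})")
    lines.append("")
    lines.append("Trait correlations (posterior mean r, 95% CI):")
    for _, row in corr.iterrows():
        lines.append(
            f"  {row['pair']:>14} [{row['variant']}]: {row['mean_r']:+.3f} "
            f"[{row['ci_low']:+.3f}, {row['ci_high']:+.3f}]"
            f"{'  *' if row['significant'] else ''}"
        )
    lines.append("")
    lines.append("Candidate linear models for mean L (ignores phylogeny):")
    for m, row in aic.iterrows():
        lines.append(
            f"  {m:>12}: k={row['k']:.0f} AIC={row['aic']:7.2f} "
            f"weight={row['aic_weight']:.3f}"
        )
    (out / "report.txt").write_text("\n".join(lines) + "\n")
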