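# beetlecomp

Comparative Bayesian analysis of **sex-biased dispersal** across bean-beetle
groups (Bruchinae: *Acanthoscelides*, *Callosobruchus*, *Zabrotes*), for
evolutionary ecologists testing whether inbreeding avoidance or kin (local
mate) competition explains variation in dispersal sex bias.

The package estimates three group-level traits from three laboratory
experiment designs, propagates their joint posterior into trait
correlations with and without phylogenetic correction, and compares
candidate linear models:

| trait | experiment | statistic |
|---|---|---|
| sex bias in dispersal | release trials on a 41-patch linear array | `L = ln(mu_F / mu_M)` from sex-specific Poisson kernels |
| inbreeding effect | 3 blocks x (2 outbred + 2 inbred) sib crosses | `delta = exp(beta_in - beta_out) - 1`, hierarchical Poisson with block and maternal-family effects |
| degree of polygyny | female x male density response surface | harem size `h` in the two-sex recruitment model `N = lambda * 2FM / (F/h + M)` |

`L > 0` is female-biased dispersal, `delta < 0` is inbreeding depression,
`h = 1` is monogamy.  All three fits are MCMC (vectorized adaptive
Metropolis with split-chain R-hat / ESS diagnostics); every posterior draw of
the trait vector yields one Pearson correlation per trait pair — raw, and
through-origin on Felsenstein's independent contrasts — so the reported 95%
credible intervals carry the full estimation uncertainty.  A synthetic-data
module generates trees (Yule), correlated Brownian-motion traits, and all
three observation tables from exactly the likelihoods the models assume, so
every stage has a parameter-recovery test.

## Worked example

```python
import beetlecomp as bc

cfg = bc.SimulationConfig(seed=3)          # 16 groups, study-sized designs
study = bc.simulate_study(cfg)             # tree + three observation tables

disp = bc.DispersalModel(study["dispersal"], n_patches=41).fit(bc.MCMCConfig(seed=3))
mat = bc.MatingModel(study["mating"]).fit(bc.MCMCConfig(seed=4))

print(disp.classify_bias().value_counts().to_dict())
print(mat.summary()[["h_mean", "h_low", "h_high"]].head(3).round(2))

r = bc.posterior_correlation(
    disp.trait_posterior("L"), mat.trait_posterior("log_h"),
    variant="pic", tree=study["tree"],
)
print(f"r(L, ln h) [PIC] = {r.mean:+.3f}, 95% CI {r.ci_95}, significant: {r.significant}")
```

prints (seed 3):

```
{'male_biased': 13, 'unbiased': 3}
       h_mean  h_low  h_high
group
G01      9.00   7.08   11.56
G02      6.47   5.13    8.08
G03     15.84  11.74   21.59
r(L, ln h) [PIC] = +0.469, 95% CI (-0.131, 0.835), significant: False
```

Thirteen of sixteen synthetic groups are significantly male-biased and every
group shown is significantly polygynous (`h_low > 1`).  The contrast
correlation is positive — sixteen independently-evolving lineages routinely
realize sample correlations of this size — but the propagated 95% interval
spans zero, so the pipeline (correctly) declares no significant association;
the defaults generate the traits with independent Brownian increments.

The same pipeline runs from the shell:

```sh
beetlecomp run --seed 3 --out results/   # simulate -> fit x3 -> correlate -> AIC table
beetlecomp report --dir results/
```

`report.txt` lists per-group bias classifications, `delta` and `h` with
credible intervals, the PIC standardization diagnostic, the four correlation
posteriors, and the five-model AIC comparison for mean sex bias (null /
inbreeding / polygyny / additive / interaction).

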