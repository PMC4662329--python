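# Methods

`beetlecomp` estimates three group-level traits of bean-beetle lineages from
three laboratory experiment designs, then asks whether the traits covary
across a clade of 16 groups, with and without correction for shared
ancestry.  This note documents the models, priors, sampler, synthetic-data
generator and the design decisions a maintainer or reviewer would want to
audit.

## Trait models

### Dispersal sex bias

Crawling displacement on a linear patch array (41 dishes, release in the
centre, so 0–20 patches of absolute displacement) is modelled per group as
Poisson per sex, pooled over release trials; beetles that died during a trial
carry no location and are dropped.  The trait is the log ratio of kernel
means, `L = ln(mu_F / mu_M)`; its sign classifies bias (female-biased above
zero, male-biased below) at the 95% equal-tailed credible level.

Priors: `mu ~ Gamma(shape 1, rate 0.1)` per sex — mean 10, essentially flat
over the 0–20 patch range, and conjugate, so the exact posterior is
`Gamma(1 + sum x, 0.1 + n)`.  The test suite holds the MCMC output against
this closed form (quantiles within 3 Monte-Carlo standard errors) and checks
frequentist coverage of the `L` interval (0.90–0.99 over 200 simulated
datasets at 30–40 observations per sex).

Deliberate simplifications, mirroring the fitted estimand: trial structure is
retained in the data but not modelled (no trial random effect), and the
likelihood ignores truncation at the array edge.  Both the generator and the
dispersal model emit a warning when edge effects are non-negligible
(truncation mass > 1%, or observed distances at the bound).

### Inbreeding effect

Each group contributes three blocks; a block holds two maternal families and
four crosses — two outbred (A×B, B×A) and two inbred (A×A, B×B).  Offspring
counts follow

    count ~ Poisson(exp(beta_type + b_block + f_family)),
    b ~ N(0, sigma_block^2),  f ~ N(0, sigma_family^2)  (families nested in blocks),

and the trait is the proportional effect of inbreeding
`delta = exp(beta_in - beta_out) - 1` (negative = inbreeding depression).
The per-block descriptive ratio `(sum_in - sum_out)/sum_out` is also exposed
(`block_delta`); on generator data the two summaries agree (Spearman > 0.9),
and the model-based `delta` is the propagated trait.  Priors:
`beta ~ N(0, 10^2)` on the log scale, `sigma ~ Half-Normal(1)` — weak at the
3–125 offspring scale.  Paternal family is retained in the data for audit but
not modelled.

Sampling parameterisation (the part worth auditing): the likelihood sees the
latent effects only through `s_jk = b_j + f_jk`, and two directions are
identified by the priors alone — the global mean of `s` against the
intercepts, and within-block family means against block effects.  The model
is reparameterised exactly into identified coordinates: within-block family
half-differences (`N(0, sigma_f^2/2)`), centred block-family means in an
orthonormal Helmert basis (`N(0, sigma_b^2 + sigma_f^2/2)`), and a global
latent mean that is integrated out analytically and re-sampled from its exact
Gaussian conditional when the raw intercepts are reported.  Without this, no
random-walk sampler mixes on the prior-identified ridge.

### Degree of polygyny

Recruitment from `F` females and `M` males follows the two-sex harmonic-mean
model

    N ~ Poisson( lambda * 2 F M / (F/h + M) ),

i.e. `lambda` times the harmonic mean of `F` and `h*M`.  `lambda` is the
reproductive rate (recruits per female at an even sex ratio under monogamy);
the harem size `h` is the trait: at `h = 1` per-capita recruitment peaks at a
1:1 sex ratio, and the optimum shifts female-ward as `h` grows (closed form
`F*/total = sqrt(h)/(1 + sqrt(h))`, reproduced numerically by
`optimal_sex_ratio`).  A denominator reading with `F*h + M` instead would
push the optimum male-ward as `h` grows, contradicting the model's defining
behaviour, and is therefore rejected.

Priors: `lambda ~ Half-Normal(50)`; `h ~ Log-Normal(log 5, 1.5^2)` truncated
to `h >= 0.1` — the heavy right tail admits extreme polygyny (h in the
hundreds) when the response surface demands it, and `h < 1` is allowed so
that "significantly polygynous" (CI entirely above 1) is a real test.
Identifiability requires at least two distinct sex-ratio cells; a fit whose
95% interval for `h` is wider than 2.5× its posterior median is flagged as
weakly identified (well-identified fits sit near 0.5–1×; the extreme-polygyny
regime sits at 2–4×).

## MCMC

All three models share one sampler (`beetlecomp.mcmc`): a vectorized adaptive
Metropolis that batches independent per-group posteriors — one pass fits
every group (or every simulated replicate, in the recovery studies) at once.
The kernel mixes, 50/50, a random-walk proposal with warm-up-adapted
covariance (Haario-style, Robbins–Monro step-size toward the canonical
acceptance rates 0.44/0.234) and an independence proposal from a multivariate
t (df 5, covariance inflated 1.3×) fitted to the warm-up history; the heavy
tails let chains enter and leave the weakly-identified tails of variance
parameters.  Models may declare Metropolis-within-Gibbs blocks (the
inbreeding sigmas get their own 2-d block) and multiplicative "scale moves"
that rescale a hierarchical scale together with its latent values — a move
along the funnel axis, Hastings-corrected with the `gamma^n` Jacobian.

Defaults: 4 chains × 2000 retained draws after 1000 warm-up iterations.
Split-chain R-hat and Geyer-initial-sequence bulk ESS are computed per group
and parameter (cross-checked against `arviz` in the tests); any R-hat above
1.01 is surfaced as a warning on the results object and in the pipeline log.
Variance components informed by only three blocks mix slowest; their
marginals are honest but their ESS can sit an order of magnitude below the
trait parameters'.

## Posterior-propagated correlations and model comparison

Every MCMC iteration supplies one trait vector across groups, hence one
Pearson correlation per trait pair: `(|L|, delta)` — bias in either direction
against the inbreeding effect — and `(L, ln h)` — signed bias against
polygyny.  The `raw` variant is the centred Pearson correlation of group
values; the `pic` variant computes Felsenstein's independent contrasts per
draw and correlates them through the origin (contrasts have mean zero and
arbitrary sign; a centred variant is available for sensitivity).  Groups
missing a trait (a taxon absent from one experiment) are pruned pairwise,
with the tree pruned to match.  Intervals are equal-tailed 95% quantiles of
the correlation draws.

Contrasts are computed by materialising the pruning recursion as a linear
operator once per tree (each standardized contrast is a fixed linear
combination of tip values), so per-draw PICs are a matrix product.  The
operator is validated three independent ways: a hand-computed 3-tip example,
`ape::pic` in R, and the identity between through-origin PIC correlation and
GLS correlation under the full Brownian covariance (equal to 1e-8 across 100
random trees).  A standardization diagnostic regresses |contrast| on its
expected SD; a slope significant at 5% flags branch lengths inconsistent
with Brownian motion.  Tree transformations (Grafen, Pagel's lambda) are out
of scope: only the untransformed pathway plus the diagnostic is provided.
Unrooted input trees are midpoint-rooted by default (outgroup rooting is
available); polytomies are rejected unless explicitly resolved to zero-length
branches, and zero-length daughter branches are nudged by 1e-8 × tree depth
with a warning.

Five candidate Gaussian linear models for posterior-mean sex bias (null;
inbreeding; polygyny; additive; interaction) are fitted by maximum
likelihood on complete cases so their AICs are comparable, with parameters
counted including the residual variance (k = 2, 3, 3, 4, 5), AIC weights as
normalized relative likelihoods, and likelihood-ratio tests against the null
on a chi-squared reference.  This stage has no group-level replication to
separate phylogenetic effects from residual variance, so it ignores
phylogeny and says so in a warning every time it runs.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the study design: 16 groups on a rooted binary tree
(unit-depth Yule simulation, or a shipped 16-tip fixture whose tip labels are
the real group abbreviations but whose topology and branch lengths are
plausible inventions); traits evolved by correlated Brownian motion
(increment covariance = `D R D * branch length`); 6 release trials of 5
beetles per sex with 5% independent mortality and resampling-truncation at
the array edge; 3 blocks × 4 crosses; a `{1,5,9} × {1,5,9}` response surface
with 2 replicates.  The nine realized density cells of the original
experiment are not recoverable from its description; the default grid is a
standard response-surface reduction spanning both sex-ratio extremes, which
is what identifies `h`.

Defaults and why: trait roots `(-0.3, -0.05, 2.3)` and BM rates
`(0.2, 0.05, 1.0)` for `(L, delta, ln h)` reproduce the reported trait
regimes — mostly male-biased dispersal around 4 patches, weak inbreeding
effects of either sign with only a minority of groups individually
significant, and strong polygyny (harem sizes ~3–30 with rare extreme tips).
The `delta` rate also keeps Brownian paths a ~5-sigma event away from the
`delta <= -1` boundary where a multiplicative effect is undefined (the
generator raises there).  Baseline scales: `mu_M = 4` patches, mean offspring
55, `lambda = 20`.  Every sampling distribution in the generator is exactly
the corresponding model's likelihood, so posterior means are consistent and
the recovery tests are meaningful; a master seed fans out into fixed
per-stage substreams, making whole studies byte-reproducible.

What passing tests do **not** show about real data: real dispersal kernels
are over-dispersed relative to Poisson and edge-truncated; real cross counts
can fail Poisson equidispersion; recruitment noise may exceed Poisson;
branch lengths estimated from molecular data carry error the pipeline
ignores (tree uncertainty is explicitly out of scope).  The generator shares
each model's idealisations, so recovery tests validate the inference
machinery, not the adequacy of the likelihoods for laboratory counts.

## Null calibration: a subtlety worth understanding

With zero between-group trait variation (BM rates 0), all observed variation
is experimental noise, independent across groups and draws; the propagated
interval for `r` then excludes zero in ≤ 10% of replicates (~5% nominal),
and the null model wins the AIC comparison in the majority of noise-only
responses.  This is the calibration the test suite enforces.

Under Brownian trait variation with *independent* increments the same
interval excludes zero far more often (~20–40%).  That is not a defect: 16
lineages evolving independently still realize a sample correlation of order
`1/sqrt(15) ≈ 0.26`, and a pipeline whose trait posteriors are tight relative
to the trait spread correctly reports that realized correlation.  The
credible interval quantifies measurement uncertainty about the realized
trait configuration — it is not a frequentist test of the evolutionary
process, and with 16 groups no such test has much power.  Interpret
single-clade trait correlations accordingly.

## Numerical choices and degenerate inputs

- Equal-tailed credible intervals throughout.
- Sex codes strictly `{F, M}`; cross type must match family labels; a
  distance must be present exactly when the beetle survived — violations are
  rejected with row numbers, never recoded.
- A sex with zero surviving observations, or a group with all-zero counts,
  skips that group with a warning; downstream joins prune pairwise.
- A single observation per sex is prior-dominated but finite (conjugate
  posterior `Gamma(1 + x, 1.1)`).
- Posterior CSVs round-trip bit-exactly (`float_precision="round_trip"` on
  read); a JSON manifest records draw counts and seeds, and draw-count
  mismatches on read-back are errors.
- All randomness flows from explicit seeds; identical configs reproduce
  identical simulation tables bit-for-bit and identical MCMC draws.

## Problem sizes used by the validation suite

Recovery and calibration studies batch simulated replicates as additional
"groups" in one vectorized fit: 200 dispersal datasets (interval coverage),
~200 inbreeding datasets split over true effects {-0.3, 0, +0.2} (bias of
the posterior mean < 0.05), 100 mating datasets at `h = 4` plus 30 each at
`h ∈ {1, 5, 25}` (factor-two recovery; interval width increasing in `h`),
and 100 full-pipeline replicates for the null calibration, fitted with
4 chains × 400–500 retained draws.
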