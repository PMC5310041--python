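# Methods

## Data model

The unit of observation is one adult damselfly with fields
`(population, year, phenotype, mites, mated, eggs)`. The pair
`(population, year)` — a *group* — is the level of every random effect: it
captures which cohort of which pond a host developed in, the scale at which
mite exposure varies. Phenotypes are the three heritable female colour
morphs (A, I, O) and males (M). Egg counts exist only for mated females and
may legitimately be zero (a 72-h oviposition window can fail), so a missing
egg count is encoded as an empty CSV field, never as 0. Males carry a mated
flag but never eggs; validation enforces this.

## Resistance model (hurdle Poisson)

Two latent processes generate a mite count:

* hurdle: `P(mites > 0) = logit⁻¹(ζ_p + a_g + e1)`, `a_g ~ N(0, σ²g,logit)`,
  `e1 ~ N(0, σ²e,logit)`;
* count: `mites | mites>0 ~ ZTPoisson(exp(η_p + b_g + e2))`,
  `b_g ~ N(0, σ²g,log)`, `e2 ~ N(0, σ²e,log)`.

The hurdle is parameterised as the probability of being **non-zero**
(prevalence); implementations must not flip this sign convention. Reported
intensity applies the zero-truncated mean `λ/(1−e^{−λ})` draw-wise (the raw
rate `λ` is available via `intensity_estimates(..., raw_rate=True)`); the
function is evaluated as `λ / (−expm1(−λ))`, which is exact and tends to 1
as λ→0.

**Identifiability of σ²e,logit.** A Bernoulli observation cannot identify a
unit-level variance on the linear predictor — it is confounded with the
scale of the fixed effects. Following standard practice for binary traits
in hierarchical animal models, σ²e,logit is therefore *fixed* (default 1.0)
rather than estimated, the unit effect is integrated out of the Bernoulli
likelihood, and the fixed value enters the prevalence variance partition
`σ²g,logit/(σ²g,logit+σ²e,logit)` as the residual term. The synthetic
generator uses the same value, so generator and fitter share one
data-generating story. The count-process over-dispersion σ²e,log *is*
identified (it inflates count variance) and is estimated, with the unit
effects e2 sampled as latent parameters.

Variance partitions use latent (link-scale) variances only; no
link-distribution variance term (π²/3 or similar) is added.

## Tolerance model (random-slope Poisson GLMM)

For mated A- and I-females:

```
eggs_i ~ Poisson(exp(α_m + (β_m + s_g)·mites_i + u_g + ε_i))
(u_g, s_g) ~ N₂(0, Σ_u)   unstructured 2×2,   ε_i ~ N(0, σ²ε)
```

Mite load enters raw (uncentred) and linearly on the log link — fecundity
declines exponentially per mite, so `exp(α_m)` is fecundity at zero mites
and `(1−e^{β_m})·100` the percent loss per mite. There is one random slope
per group, shared by both morphs (the 2×2 structure). Zero-egg mated
females are retained — Poisson support includes 0 and a hurdle on fecundity
is not part of the model. O-females are excluded by default; a flag fits
them with a warning, but with ~5% of matings their group-level reaction
norms are poorly identified.

## Priors

The original analysis used vague priors whose exact hyperparameters are not
recoverable; defaults here are weakly informative and their influence at
the sample sizes used is negligible:

* fixed effects: Normal(0, 10²);
* standard deviations: half-Student-t(3, scale 2); for the tolerance
  model's group intercept/slope sds the scale is 1 (group heterogeneity on
  the log-egg scale is well below 1 in magnitude, and a tighter scale keeps
  the implied variance prior proper without being informative at the
  0.001–0.3 magnitudes that matter);
* Σ_u is decomposed into two sds and a correlation with a uniform(−1, 1)
  prior, avoiding inverse-Wishart degeneracies at 40 groups.

## Sampler

No probabilistic-programming backend is used; both posteriors are sampled
with a blocked adaptive Metropolis-within-Gibbs scheme written for these
two model families (`mitedef/_mcmc.py`):

* conditionally independent blocks (phenotype effects, group effects, unit
  effects) are updated with vectorised random-walk proposals, step sizes
  Robbins–Monro-adapted to 0.44 acceptance during burn-in and frozen
  afterwards;
* every variance component is updated in both the centred and the
  non-centred parameterisation each sweep (ancillarity–sufficiency
  interweaving), which keeps scales mobile whether or not the underlying
  effects are well identified — essential for σ²ε with one observation per
  unit effect;
* likelihood-invariant translation moves shift each fixed effect against
  the mean of the random effects it is confounded with (intercepts against
  group/unit intercepts; slopes against group slopes and against unit
  effects weighted by mite load). These moves cost only prior evaluations
  and remove the slow ridge walks that otherwise dominate mixing;
* the smeared Bernoulli probability `E[logit⁻¹(μ + σZ)]` is a fixed smooth
  function of μ (σ fixed), tabulated once per fit on a 0.005 grid over
  [−30, 30] by 41-node Gauss–Hermite quadrature and interpolated (error
  ≪ 1e−6, far below Monte-Carlo noise);
* zero-truncated Poisson log-mass uses `log(−expm1(−λ))`; linear predictors
  are clipped at ±30 before exponentiation.

The default ("reduced") schedule is 2 chains × (1500 burn-in + 2000 sweeps,
thin 2) = 1000 kept draws per chain, giving R̂ ≤ 1.01 and ESS of several
hundred for all reported parameters at the study-mimic sizes (~20 s for the
20 000-record resistance fit, ~12 s for the 3840-record tolerance fit). The
published schedule (1 chain, 100k burn-in, 2M sweeps, thin 1000) is
available as `MCMCSchedule.paper()` / `--paper-schedule`. Chains start from
moment-based estimates with overdispersed jitter; with ≥2 chains the
Gelman–Rubin diagnostic is computed from the classical between/within
variance formula, ESS by the initial-positive-sequence estimator, and
fits are exactly reproducible given (data, schedule, seed).

## Derived statistics

* **pMCMC** — the fraction of paired draws whose sign opposes the sign of
  the posterior mean difference, floored at 1/n. The one-sided form is the
  default; a doubled ("two-sided") convention is available and every result
  records which convention produced it. Draws estimated in separate models
  are paired by independent resampling.
* **Virulence** — `V_m = 1 − b_m^{I_m}` with `b_m = e^{β_m}` and `I_m` the
  morph's intensity on the count scale (truncated mean by default, raw rate
  optionally). The two marginals are independently resampled with
  replacement to 2000 paired draws. V is 0 when b = 1 or I = 0, increasing
  in I and decreasing in b.

## Synthetic-data generator

The generator draws surveys from exactly the processes the models assume —
the same link functions, random-effect structure and additive
over-dispersion — so recovery tests probe the inference machinery, not
model misspecification. Mite counts for the fecundity survey come from the
same infection process (fresh group effects), giving realistically
clustered, zero-heavy mite distributions. Zero-truncated Poisson variates
are drawn by inversion of the truncated CDF (exact at any rate; rejection
sampling stalls at small rates). The group effects of the two resistance
processes are drawn independently (no cross-process correlation is
modelled).

The frozen **study-mimic configuration** (`paper_mimic_config`) encodes the
published point estimates as generating values:

| quantity | value | source/choice |
|---|---|---|
| per-mite loss A / I | β = ln 0.963 / ln 0.917 | reported 3.7% / 8.3% |
| zero-mite fecundity A / I | exp(α) = 242.4 / 322.4 | reported 80-egg gap and 1.33 ratio |
| prevalence variance share | 0.656 | reported; σ²e,logit ≔ 1.0 ⇒ σ²g,logit = 1.907 |
| intensity variance share | 0.366 | reported; σ²e,log ≔ 0.30 ⇒ σ²g,log = 0.173 |
| group slope variance | 0.003 (cov 0) | reported posterior mean; covariance not printed |
| group intercept variance | 0.045 | ≈8% of log-egg variance, inside the reported 5.2–11.3% |
| residual fecundity variance | 0.50 | plausible over-dispersion for 72-h egg counts |
| marginal prevalences A/I/O/M | 0.22 / 0.20 / 0.12 / 0.145 | reproduce the ~84% zero fraction under the reported ordering; ζ solved by quadrature |
| intensity levels η | 1.1 / 0.6 / 1.4 / 0.9 | placeholders on the reported ordering (O > A > M > I); no numeric values are printed |
| design | 10 populations × 4 years; 104/35/10/351 A/I/O/M per group (20 000 hosts); 63 A + 33 I mated per group (3840 females) | ~40 groups with the reported 5517 : 1856 : 518 : 18 786 and 2517 : 1303 imbalances |

What the generator does **not** emulate: within-season visit structure,
copula-pair linkage between males and females, morph-frequency dynamics,
any resistance–tolerance correlation at the individual level, and
non-Poisson features of real egg counts (e.g. handling-induced zero
inflation). Passing recovery tests therefore demonstrate correct inference
under the assumed model at realistic sizes and imbalance — not robustness
to field-data pathologies.

## Recovery-study design

A single simulated survey has only 40 groups, so the *realized* group
effects deviate appreciably from their nominal variances (e.g. the sample
variance of 40 logit-scale group effects has SD ≈ 0.43 around 1.907, ≈ 5
percentage points on the prevalence variance share; the realized mean group
slope shifts both morphs' fecundity slopes by ≈ 1 pp). The fitted
posteriors track each survey's realized effects closely, so recovery of the
*nominal* generating values is assessed by averaging posterior means over
independently seeded replicate surveys: six for the tolerance model, three
for the resistance model (the acceptance script derives replicate seeds
from its `--seed`). Slope-contrast detection (pMCMC) is evaluated per
replicate.

Problem sizes throughout (20 000-host resistance surveys, 3840-female
fecundity surveys, the reduced schedule, 20-replicate coverage checks at
smaller sizes) were chosen as the smallest designs at which the published
quantities are identifiable with the precision the recovery tolerances
require.

## Degenerate and edge cases

* All-zero mite counts: the count process has no data; its parameters
  revert to their priors while prevalence concentrates near 0.
* Constant draw sequences: autocorrelation is defined as 0 and ESS as n,
  with a warning.
* Single-morph fecundity data: the slope contrast is undefined and the fit
  refuses explicitly.
* Record order: all sufficient statistics are order-invariant, so permuting
  records reproduces the identical posterior.

## Known limitations

* The random-walk sampler, while adequate at these sizes, scales worse than
  gradient-based samplers; very large surveys (≫10⁵ records) would warrant
  a different backend.
* The fixed σ²e,logit means prevalence variance shares are interpretable
  only relative to the chosen residual scale (as with any binary-trait
  variance partition).
* Reaction-norm uncertainty bands are fitted-mean bands
  (`predict_fecundity`), not posterior-predictive bands for new
  observations.
* Fecundity tolerance only; survival tolerance and male fitness are out of
  scope.
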