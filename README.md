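# mitedef

Bayesian analysis of parasite defence in a colour-polymorphic damselfly:
**resistance** (how many water mites a host carries), **fecundity
tolerance** (how steeply egg production falls per mite), and the **virulence**
each female morph consequently experiences.

The package is aimed at evolutionary ecologists working with long-term
field surveys of *Ischnura elegans*-type systems: individuals are scored for
population, year, phenotype (androchrome A, *Infuscans* I,
*Infuscans-obsoleta* O females, or male M), water-mite count, and — for
females caught in copula — a 72-h egg count. Because such surveys are rarely
deposited, a first-class synthetic-survey generator with the same
hierarchical structure is included, and all inference code is validated by
parameter recovery against it.

## Models

**Resistance — zero-altered (hurdle) Poisson GLMM.** Mite counts are mostly
zero (~84% of hosts), so prevalence and intensity are modelled separately.
With phenotype *p* and population-by-year group *g*:

```
infected_i ~ Bernoulli(logit⁻¹(ζ_p(i) + a_g(i) + e1_i))          e1 ~ N(0, σ²e,logit)
mites_i | infected ~ ZTPoisson(λ_i),  log λ_i = η_p(i) + b_g(i) + e2_i,  e2 ~ N(0, σ²e,log)
```

Prevalence is `logit⁻¹(ζ_p)`; intensity — the expected count in parasitized
hosts — is the zero-truncated mean `λ/(1−e^{−λ})`. Both processes carry
their own group variance and additive over-dispersion; the share
`σ²g/(σ²g+σ²e)` quantifies spatio-temporal variation.

**Tolerance — random-slope Poisson GLMM.** For mated A/I females, eggs
decline exponentially with mite load at a morph-specific rate:

```
eggs_i ~ Poisson(exp(α_m(i) + (β_m(i) + s_g(i))·mites_i + u_g(i) + ε_i))
(u_g, s_g) ~ N₂(0, Σ_u),   ε ~ N(0, σ²ε)
```

`(1−e^{β_m})·100` is the percent fecundity loss per mite — a flatter slope
means a more tolerant morph.

**Virulence.** With retention base `b_m = e^{β_m}` and intensity `I_m`, the
proportional fitness loss is `V_m = 1 − b_m^{I_m}`, computed by pairing 2000
independent resamples of the two marginal posteriors.

Models are sampled by a built-in blocked adaptive Metropolis-within-Gibbs
sampler (interweaved variance updates, likelihood-invariant translation
moves); convergence is checked with Gelman–Rubin R̂, autocorrelation and
effective-sample-size diagnostics. Posterior contrasts are reported with
pMCMC — the fraction of draws opposing the sign of the mean difference.

## Worked example

```python
import mitedef as md

cfg = md.paper_mimic_config(seed=1)          # study-mimic generating config
survey = md.simulate_fecundity_survey(cfg)   # ~3840 mated A/I females, 40 groups
post = md.fit_tolerance(survey, seed=1)      # ~15 s, 2 chains x 1000 draws

for morph in ("A", "I"):
    s = md.percent_decrease_per_mite(post.beta_draws(morph))
    print(f"{morph}: {s['mean']:.1f}% per mite (95% CI {s['ci_low']:.1f}-{s['ci_high']:.1f}%)")
c = md.intercept_contrast(post)
print(f"zero-mite fecundity gap: {c['difference']['mean']:.1f} eggs, "
      f"ratio {c['ratio']['mean']:.2f}, pMCMC {c['pmcmc']:.4f}")
```

prints

```
A: 2.9% per mite (95% CI 0.7-5.3%)
I: 8.7% per mite (95% CI 5.6-11.9%)
zero-mite fecundity gap: 94.7 eggs, ratio 1.38, pMCMC 0.0005
```

i.e. on this simulated survey the fitted reaction norms recover the
generating per-mite losses (3.7% for A, 8.3% for I) within posterior
uncertainty, and I-females are correctly estimated to out-produce A-females
in the absence of parasites but to pay a steeper per-mite cost.

The same analysis is available from the shell:

```
mitedef simulate --fecundity --seed 1 --out fec.csv
mitedef fit-tolerance fec.csv --out tolerance_draws.csv
mitedef fit-resistance survey.csv --out resistance_draws.csv
mitedef report --resistance-draws resistance_draws.csv \
               --tolerance-draws tolerance_draws.csv --out report.json
```

or end-to-end with `mitedef pipeline --outdir results --seed 1`.

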