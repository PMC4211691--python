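# espanola

Demographic and ecological analysis toolkit for assessing a giant-tortoise
repatriation program, modeled on the five-decade restoration of
*Chelonoidis hoodensis* on Española Island (Galápagos): roughly 1,500
captive-bred tortoises released at three sites from 1975 onward, monitored
by mark-recapture, and embedded in a severely woody-encroached landscape
where the arboreal *Opuntia* cactus is the key tortoise resource.

The package is aimed at quantitative ecologists who want the full analysis
chain behind such an assessment as tested, reusable code:

- **`espanola.markrecap`** — a Bayesian open-population mark-recapture model
  (Cormack–Jolly–Seber variant) for a population founded entirely by known
  releases. Apparent survival φ is age-structured (year-of-release rate,
  juvenile < 8 y, adult ≥ 8 y) and time-blocked (1/2/4-year blocks); capture
  probability p has young/adult means (< 15 / ≥ 15 y) and a logit-normal
  annual random effect: `logit(p_t) = logit(p_class) + ε_t`,
  `ε_t ~ N(0, σ_p²)`. The likelihood is the multinomial over the m-array
  (first-recapture counts by cohort), which marginalizes latent alive/dead
  states exactly; abundance of released survivors is recovered by cohort
  propagation.
- **`espanola.projection`** — female-only stochastic age-structured
  projection with ceiling density dependence, Poisson recruitment, uniform
  parameter bounds with perfectly correlated fertility components
  (fertility = proportion female × eggs/female × hatching success ×
  hatchling survival), quasi-extinction risk (75-adult threshold), three
  management scenarios, R_max via Leslie matrix / Euler–Lotka, and an
  approximate-likelihood estimator of the hatching × hatchling-survival
  product from the observed rise in native-born tortoises.
- **`espanola.habitat`** — Bayesian negative-binomial regression of plot
  counts of tortoises on distance to release sites, adult cactus density,
  and woody stem density (log-area offset); carrying-capacity extrapolation
  at distance zero; restoration scenarios; Williams-corrected G-test and
  percent changes for the cactus stage censuses.
- **`espanola.movement`** — displacement rates, minimum-convex-polygon
  range areas, a 500-replicate permutation null for range expansion
  (starting locations de-linked from displacement vectors), and the
  edge-orientation regression.
- **`espanola.isotopes`** — soil δ¹³C end-member classification (woody
  −26 to −30‰ vs herbaceous/cactus −13 to −16‰), radiocarbon depth–age
  calibration, and the two-period (≤ 40 cm vs deeper) trend test for woody
  encroachment.
- **`espanola.synthetic`** — generators for every input table with the
  statistical structure the analyses assume; no field data are published,
  so all tests run on synthetic data.

## Worked example

```python
from espanola.habitat import williams_g_test, percent_change
from espanola.projection import ProjectionConfig, leslie_lambda, run_scenario

# cactus stage structure in the release-zone macroplot, 2004 vs 2014
res = williams_g_test((194, 121), (266, 130))
print(f"G_adj = {res.g_adj:.2f}, df = {res.df}, P = {res.p_value:.2f}")
print(f"total +{percent_change(315, 396)}%, juv/subadult "
      f"+{percent_change(194, 266)}%, adult +{percent_change(121, 130)}%")

# maximum population growth rate from the estimated vital rates
rates = {"age_first_reproduction": 17, "proportion_female": 0.5,
         "eggs_per_female": 7.0, "hatching_success": 0.205,
         "hatchling_survival": 0.205, "survival_age_1_3": 0.75,
         "phi_juvenile": 0.958, "phi_adult": 0.977}
print(f"R_max = {leslie_lambda(rates):.4f}")

# quasi-extinction risk if repatriation stops
out = run_scenario(ProjectionConfig(seed=1), "terminate")
print(f"extirpation probability: {out.extirpation_probability:.1f}%")
```

prints

```
G_adj = 2.39, df = 1, P = 0.12
total +26%, juv/subadult +37%, adult +7%
R_max = 1.0120
extirpation probability: 0.0%
```

i.e. the cactus population grew 26% with no significant shift in stage
structure, the vital rates imply a weakly positive growth rate (R_max just
above 1), and the repatriated population faces negligible 100-year
extinction risk even if releases stop.

A command-line interface mirrors the library
(`espanola simulate|fit-cjs|project|habitat|movement|isotopes ...`); run
`espanola --help`.

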