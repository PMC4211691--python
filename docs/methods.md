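# Methods

This note documents the models, the defaults and why they were chosen, the
synthetic data the tests run on, and the numerical choices that a user of
the package should know about.

## Mark-recapture model (`markrecap`)

**Model.** Open-population capture-recapture (Cormack–Jolly–Seber family)
for a population founded entirely by known releases between 1975 and 2007.
Apparent survival φ over the interval following occasion *t* depends on the
individual's age and release status:

- year-of-release survival φ_R, one parameter per release year, applied to
  the first interval after release (it *replaces* the class rate for that
  interval — release stress and young age make the first year distinct);
- juvenile survival φ_J (age < 8), one parameter per 2-year block;
- adult survival φ_A (age ≥ 8), one parameter per 4-year block.

Blocks are anchored at the first survey year; an incomplete trailing block
is absorbed into the last full one. Capture probability has class means
p_young (age < 15) and p_adult (≥ 15) and a shared annual random effect on
the logit scale, ε_t ~ N(0, σ_p²). Priors are U(0,1) on all probabilities
and U(0,5) on σ_p. Survey years without recapture effort (1995, 1996, 1998
by default) get p_t ≡ 0, so intervals bridge across them with compounded
survival.

**Likelihood.** Rather than tracking each individual's latent alive/dead
state, the fit uses the multinomial likelihood over the m-array: for each
cohort (entry occasion × entry age × newly-released flag) the counts first
recaptured at each later occasion and the count never seen again. Each
detection re-enters the individual as a re-encounter cohort. This
marginalizes the latent states exactly — the test suite verifies equality
with brute-force enumeration over latent death times to 1e-10 — and makes
the likelihood deterministic and cheap. Cohorts with identical probability
rows (ages capped at the capture-class threshold, beyond which age no
longer matters) are merged.

**Sampler.** Blocked adaptive random-walk Metropolis on transformed
parameters (logit for probabilities, log for σ_p, ε free), with
per-coordinate proposal scales from a running variance estimate and a
per-block step size tuned toward ~30% acceptance during burn-in only.
Default schedule: 3 chains, 5,000 burn-in + 10,000 kept iterations thinned
by 10. Convergence is summarized by the Gelman–Rubin potential scale
reduction factor per parameter. The survival- and capture-dependent halves
of the cell probabilities are cached separately, since block updates touch
only one half at a time.

**Class-level summaries.** The block-level survival draws are combined into
a class-level rate by weighting blocks with their exposure (individuals
entering the intervals a block governs). Data-free blocks, whose posterior
is just the prior, therefore do not dilute the class summary. The terminal
survival block shares the classic CJS confound with final-year capture
probability and is the least reliable parameter — its information comes
mostly through the shared capture random effect.

**Abundance.** Expected released survivors per region (the two central
release sites are pooled; Gardner Bay is separate) are obtained per
posterior draw by propagating each release cohort through φ_R and the
age-appropriate block rates. Abundance can therefore never exceed
cumulative releases. Native-born individuals are excluded from both the fit
and the abundance (they enter only the fertility estimator).

**Growth records.** The screening rule drops recapture intervals longer
than 3 years, then trims the lowest and highest 2.5% of annualized growth
rates (sort-and-slice; ties resolved by record order). Growth/condition
model fitting itself (a GAMM problem) is out of scope here.

## Population projection (`projection`)

Female-only, age-structured (1-year classes to a terminal self-looping
class at age 45), annual time step, 100 replicates × 150 years from 2011 by
default.

Per replicate, uncertain inputs are drawn uniformly from their bounds: age
at first reproduction 17 (fixed), proportion female 0.3–0.7, carrying
capacity K 424–3,921, eggs per female 4–10, survival at ages 1–3 0.6–0.9,
hatching success 0.15–0.26, hatchling survival 0.15–0.26. The four
fertility components share a single uniform quantile (perfect rank
correlation) — a conservative choice that widens the spread of outcomes.
Juvenile (0.958) and adult (0.977) survival enter as point estimates from
the mark-recapture stage, with a shared annual logit-normal deviation
(default SD 0.35, chosen to reproduce block-to-block spread of the
estimated survival series; `CjsPosterior.temporal_sd_logit()` supplies a
data-driven value).

Yearly update: binomial survival per age class → Poisson recruitment
(breeding females ≥ 17 × total fertility) → aging (recruits enter age 1)
→ ceiling truncation → scenario releases/removals. Quasi-extinction is
flagged when adult females (≥ 18) fall to or below 75 at any time;
risk is reported over a 100-year window inside the 150-year horizon.

Choices made where the design was genuinely open:

- **Initial abundance.** The female-only model starts from the 864 released
  tortoises estimated alive in 2007, used directly as the initial female
  abundance (the assessment approximated it that way); a config flag
  instead scales it by the replicate's proportion-female draw. Initial ages
  come from the historical release schedule (age ≈ 4 at release plus
  elapsed years).
- **Ceiling.** K is applied to the model's population vector (females).
  Applying only the female share of K would truncate the starting
  population to a few hundred for low K × low proportion-female draws and
  park adults near the quasi-extinction threshold — dynamics incompatible
  with the assessment's reported low risk and decades-long approach to K.
- **Ceiling removal policy.** Excess is removed youngest-first
  (recruitment is suppressed while the population sits at K). Removing
  uniformly across ages lets large hatchling pulses displace adults at the
  ceiling, which is backwards for a long-lived iteroparous species where
  density dependence falls on early stages; `ceiling_policy="uniform"`
  restores the alternative.
- **Scenarios.** Continued repatriation defaults to 40 female juveniles
  released annually at age 4 for 25 years (the historical program averaged
  ~46 releases/year; the exact future rate is a management choice, so it is
  prominently configurable). Termination-plus-removal removes 50 adult
  females at the start. Scenarios run under common random numbers (the
  replicate index, not the scenario, keys the random substream), so
  scenario contrasts such as the year K is first reached are not washed out
  by between-scenario Monte Carlo noise.
- **Quasi-extinction threshold.** 75 is interpreted on the modeled sex
  (adult females); `count_threshold_as_total_adults=True` halves it to
  approximate a total-adult reading.

**R_max.** `leslie_lambda` builds the female Leslie matrix (post-breeding
convention; classes 1..17 with the terminal class self-looping at adult
survival; fertility f = the four-way product, which already carries
offspring through their first year, entering the first row from the
breeding class). `euler_lotka_lambda` solves the renewal equation
`1 = f λ^(−m) l_m / (1 − φ_A/λ)` by bisection; the two agree to 1e-8 over
random rate sets, and both give R_max = 1.01 at the estimated rates.

**Fertility estimator.** The hatching × hatchling-survival product g is
estimated by grid search: for each g the released population and its
native-born offspring are propagated in expectation from the release
schedule, the simulated native-born fraction trajectory is scored against
observations by sum of squared deviations, and all grid values scoring
within 2× the minimum are accepted (a pragmatic acceptance band; the
original approximate-likelihood cutoff is not published). Endpoints map to
per-component values by the square root, the two components being assumed
equal — g = 0.0225 ⇔ both at 0.15.

## Habitat (`habitat`)

Counts of tortoises per plot (five pooled 20-m-radius sub-plots, ≈ 0.63 ha)
are negative binomial with log mean = log(area) + β₀ + β·z, covariates
z-scored (coefficients reported on both scales). The log-area offset makes
the intercept a log density per hectare, so carrying capacity is
`K = exp(η(distance = 0, zone-mean covariates)) × zone area` per posterior
draw (1,250 ha zone by default; the assumption is that density at the
release sites has equilibrated). Restoration scenarios re-evaluate the same
log-linear prediction under altered covariates, so the combined scenario is
exactly multiplicative in K. The sampler is the shared adaptive Metropolis
(30,000 iterations, 10% burn-in, thin 10); priors are weakly informative
normals (SD 10 on standardized coefficients, SD 2 on log dispersion) —
effectively flat over the supported region. Whether the original regression
used an area offset is not stated; the offset is this package's choice and
is documented here.

The Williams-corrected G-test uses G = 2 Σ O ln(O/E) with divisor
q = 1 + [(N/r₁ + N/r₂ − 1)(N/c₁ + N/c₂ − 1)]/(6N) and a χ²₁ upper-tail
p-value. On the printed census table it evaluates to G_adj = 2.385
(reported as 2.38 at two decimals in the assessment — the formula above
rounds to 2.39, a half-ULP discrepancy presumably from intermediate
rounding in the original).

## Movement (`movement`)

Coordinates are planar metres (inputs are assumed projected; the package
does no geographic reprojection). MCP areas come from the convex hull
(shoelace area, reported in hectares); degenerate inputs (< 3 distinct or
collinear points) give a flagged zero-area polygon. The permutation null
permutes starting locations among individuals, re-attaches each observed
displacement vector, and recomputes the hull of initial + final points, 500
replicates by default; permutation is global across individuals
(within-class permutation is a documented alternative the caller can apply
by subsetting). The edge-orientation response is the cosine between the
displacement and the inward direction at the start (from the nearest
boundary point toward the start; the centroid direction substitutes on the
boundary itself), regressed by OLS on distance to the edge: a negative
slope means edge-adjacent animals orient inward more strongly.

## Isotopes (`isotopes`)

Species are assigned to the woody or herbaceous-like δ¹³C pool by proximity
to pool centres (hinted species or a largest-gap split); exact ties are
flagged ambiguous rather than silently assigned. Depth–age calibration is
piecewise linear through (0 cm, 0 BP) and the radiocarbon anchors (default
40 cm → 510 BP, 60 cm → 1100 BP), extrapolating the deepest segment's rate
to at most 1.5× the deepest anchor; the surface anchor is an assumption.
The trend test regresses δ¹³C on depth separately above and below the
regime boundary (default 40 cm ≈ 510 BP), with soil pit as an additive
fixed term — two pits cannot support a random-effect variance, so the
original's random pit effect is deliberately simplified; with one pit the
term is dropped with a warning. Depth (not calibrated age) is the default
predictor; the age model is reported alongside.

## Synthetic data (`synthetic`)

The generators emulate the study's structure: ~1,482 releases over
1975–2007 at three sites (weights from the recapture-database cohort
sizes); capture histories from the exact generative model the CJS fit
assumes (survival ~0.96–0.98, capture ~0.33–0.38, logit SD 0.3, no surveys
in 1995/1996/1998); negative-binomial plot counts with configurable slopes;
movement with isotropic or edge-avoiding steps inside a polygon; two-regime
δ¹³C profiles mixing woody (−28‰) and herbaceous (−14.5‰) end members with
a linear woody-fraction trend above 40 cm; and multinomial two-period
cactus censuses (totals 315 and 396 by default). Every generator is a pure
function of (config, seed); substreams are derived per generator, so adding
one never perturbs another.

What the synthetic data do **not** emulate: spatial heterogeneity of survey
effort, individual heterogeneity in survival or detectability, movement
between release regions, tag loss, measurement error in covariates, and
real vegetation maps. Passing tests therefore demonstrate correctness of
the estimators under their assumed models and calibration of the null
procedures — not robustness to the field-data pathologies a real dataset
would carry.

## Problem sizes and numerical choices

- The parameter-recovery test fits 20 synthetic datasets of the program's
  full scale (~1,500 releases, 33 survey years) with single short,
  well-initialized chains (2,000 burn-in + 2,000 kept, thin 5); class-level
  posterior means then sit within 0.03 of truth and per-block 95% intervals
  cover truth ≥ 90% of the time. Production fits should use the default
  3 × 15,000 schedule.
- Acceptance of a proposal compares log posteriors; −inf (out-of-support)
  proposals are always rejected. Probabilities are clipped away from {0, 1}
  only inside logs, never in the stored draws.
- The multinomial "never seen again" probability is floored at 1e-300
  before the log; cohort cells in excluded years are structurally zero and
  rejected if data ever land there.
- The bisection for the Euler–Lotka root runs on (φ_A + 1e-9, ≥ 2.0) to
  tolerance 1e-12; zero fertility returns φ_A (the matrix becomes
  triangular and the self-loop dominates).
- `percent_change` rounds halves away from zero, matching the reported
  integers (+26, +37, +7).

## Known limitations

- Strata share no information; a hierarchical pooling of the sparse Gardner
  stratum would be the natural extension.
- The CJS terminal block and final-year capture probability are only
  weakly separable (inherent to the design, not the implementation).
- The fertility estimator scores a deterministic expectation path, not a
  stochastic ensemble, and its 2×-minimum acceptance band is a proxy for an
  unpublished criterion.
- The projection has no density dependence other than the ceiling, no
  two-sex structure, and no genetics.
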