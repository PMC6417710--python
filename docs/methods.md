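# Methods

This note documents the statistical procedures, the synthetic-data
model, the numerical choices, and the limitations of `covermix`.

## Experimental design encoded in the catalog

The catalog hard-codes the trial design: 18 species, three per
functional group (CG, CL, CB, WG, WL, WB), with pure-stand broadcast
seeding rates in g m⁻² (the three cool-season brassicas revised from
1.7 to 1.1 g m⁻² in the second year); 40 treatments — a no-cover
control, 18 pure stands, single-group three-species mixtures, two-group
six-species mixtures, one-of-each-group three-species mixtures arranged
so every species appears exactly once per trio, nine-species
single-season mixtures and the full 18-species mixture; 11 sites with
four blocks each (three at site 11), treatments 1–20 at the 2013 sites
and 1–40 at the 2014 sites. Mixtures are substitutive: each species is
seeded at its pure-stand rate divided by mixture richness, so a
mixture's total seeded mass equals the mean of its constituents'
pure-stand rates. Biomass sampling uses one 0.18 m² quadrat per plot,
two at site 3; weed biomass exists at sites 3, 10 and 11 only. One of
the 2014 broadleaf rows is group-labelled WB in the catalog although
some summaries elsewhere print the cool-season code; the species
composition makes the warm-season assignment unambiguous.

## Analysis procedures

**Quadrat aggregation.** Site 3's two quadrats are averaged per plot
before every analysis, giving 80 plot-level observations there
(20 treatments × 4 blocks). This is what makes the null invasibility
model's residual df 79 at site 3, 159 at site 10 (40 × 4 − 1) and 119
at site 11 (40 × 3 − 1): all sampled plots of a site, controls
included, enter each fit.

**Volunteers.** A cover species recorded in a plot where it was not
seeded is an invader by the logic of the invasibility analysis, so it
is reclassified as a weed taxon (`volunteer:<code>`), with the moves
logged.

**Effect sizes.** Contrasts are computed per site × block and are
missing whenever any component plot is missing (listwise at block
scope). The pooled SR family concatenates the three within-group
estimates and the one constant-functional-richness estimate per block
with equal weight: 4 estimates × 27 blocks = 108 when complete.
Warm-season treatments (21–40) are excluded from all contrasts — their
replication is half that of the cool-season set and their sampling is
known to under-measure shed foliage — but per-treatment summary means
still cover them. Inference is a two-sided one-sample *t* on the pooled
block-level estimates with n − 1 df; 50% and 95% CIs use the same *t*
machinery. Block-level estimates are treated as independent, which
understates clustering within sites; the package reproduces that simple
design deliberately rather than switching to a mixed model.

**Invasibility.** BR is computed against the arithmetic mean weed
biomass of the site's control plots. The exponential models are fitted
by Levenberg–Marquardt least squares with an analytic Jacobian.
β₁ is initialized from a zero-intercept regression of
ln(max(10⁻⁶, 1 − BR/100)) on x using points with BR < 99, with a
restart ladder over {1, ½, 2}× that start; β₂ starts at 0. SEMs are the
classical Jacobian-based estimates, √(σ̂²·diag((JᵀJ)⁻¹)) with
σ̂² = SSE/df; RMSE is √(SSE/df); estimates and SEMs are reported ×10³.
The richness modifier R uses realized richness by default (a seeded but
absent species cannot suppress weeds in the quadrat); a flag switches
to seeded richness. Nested models are compared with the
extra-sum-of-squares F = (SSE₀ − SSE₁)/(SSE₁/df₁) on (1, df₁) df. The
prediction is exactly 0 at x = 0 and bounded above by 100 whenever
β₁ + β₂R ≤ 0; the exponent is clipped at 500 during optimization so
wild intermediate parameter values stay finite.

**Stability.** Per treatment × site (control excluded, ≥ 2 plots
required — 173 cells for the full design), the sample mean and
sample SD (n − 1) of plot biomass. OLS through the origin on {m} or
{m, m·R}; the base-model slope has the closed form Σ(sd·m)/Σ(m²) and
estimates the typical plot-to-plot CV. Richness enters only through the
interaction m·R, never as a main effect, and uses seeded richness by
default (the insurance argument concerns what was sown). CV
diagnostics report Pearson correlations of CV with realized richness
and with mean biomass; the negative CV–mean correlation is the
productivity confound that motivates regressing SD on the mean instead.

## The synthetic trial generator

The generator emulates the seven sampled sites of the design (3, 4, 5,
7, 8, 10, 11) with their block counts, treatment lists and quadrat
counts, and known ground truth for every downstream stage.

* **Mixture expectation.** A species' pure-stand mean μ_s predicts its
  mixture contribution. Expected mixture biomass is the
  dominance-weighted average `mult · Σ share·μ·c / Σ share·c` with
  equal seeded shares and dominance weights c = μ^γ (γ = 1 by default).
  This deliberately encodes the null mechanism — no complementarity
  bonus — so a mixture can never out-produce its best constituent, and
  a pure stand reduces exactly to mult·μ.
* **Species means** (g m⁻²) are ordered as the trial consistently
  found: cool-season grasses ≈ 300 and brassicas ≈ 350 versus legumes
  ≈ 60; sorghum sudangrass and buckwheat dominate the warm-season set.
  With γ = 1 these defaults imply closed-form contrast effects of
  ≈ +2% (pooled SR), ≈ +27% (FR) and ≈ +30% (SR & FR) — the
  low-legume drawdown mechanism, not overyielding.
  `legume_drawdown_scenario` isolates it further by equalizing means
  within groups (within-group SR contrasts exactly 0) and setting
  legumes to 20% of the grass/brassica mean.
* **Noise.** Multiplicative lognormal factors with mean exactly 1:
  per-species plot noise (CV 0.30), a per-block effect (CV 0.15), and
  weed noise (CV 0.35). Biomass is positive and right-skewed, and the
  combined plot-to-plot CV of totals is about one-third, which is what
  the SD~mean slope estimates. Because species noise is independent
  across species, mixtures average some of it away — a weak portfolio
  effect that makes the fitted BIOM:SR interaction slightly negative
  even though no stabilizing mechanism is configured; a shared
  plot-level noise component would remove this but is intentionally
  out of scope of the config.
* **Weeds.** At weed-sampled sites, weed biomass is
  `w̄_control · exp(β₁x) · noise` with the plot's realized cover total
  x and per-site rates β₁ = −0.057, −0.0069, −0.0068 per g m⁻² for the
  site-3, site-10 and site-11 analogues (steeper at the low-biomass
  site), w̄_control = 100 g m⁻². Control plots have empty cover maps
  and BR scattered around 0.
* **Dropout.** In mixtures where the seeded share 1/richness is below
  1/6, each species is independently missing from a quadrat with
  probability 0.30, so realized richness falls increasingly below
  seeded richness at richness 9 and 18. Surviving species' shares are
  renormalized so the plot's expected total biomass is unchanged:
  dropout is modelled as a realized-richness phenomenon (detection and
  local competitive exclusion in a 0.18 m² quadrat), not a biomass
  loss — deleting the biomass instead would depress every high-richness
  treatment by the dropout rate and distort the diversity contrasts
  the generator exists to exercise.
* **Seeding.** One master seed; each site draws from an independent
  substream keyed by (seed, site_id), so adding or removing a site
  leaves the others byte-identical.

What the generator does **not** emulate: volunteer cover species, weed
community composition (a fixed 60/40 genus split carries the total),
spatial autocorrelation, site × species interactions beyond a scalar
productivity multiplier, missing plots, and measurement error in
species separation. Passing tests therefore validate the statistical
machinery and the design bookkeeping, not field realism.

## Numerical and inferential caveats

* **Ratio-estimator bias.** Effect sizes are ratios of noisy means;
  with the default noise the per-block estimates inflate by a few
  percentage points relative to the closed-form values (Jensen's
  inequality). Tests therefore compare noisy runs against ground truth
  through CIs or generous margins, and exact equality only on
  noise-free runs.
* **Control-mean normalization.** BR divides by a control mean
  estimated from 3–4 plots. That normalizer's sampling error is a
  site-wide correlated amplitude error which classical NLS SEMs cannot
  see: in simulation, 95% Wald CIs for β₁ cover the generating value
  only ~35% of the time when BR uses the estimated control mean, versus
  ~94% (median relative error ~3%) when BR uses the known generating
  mean. The pipeline keeps the estimated-control-mean procedure for
  data analysis; parameter-recovery validation passes
  `control_mean=` to isolate the fitting machinery. Analysts should
  treat printed β₁ SEMs as conditional on the control normalization.
* **Degenerate inputs.** Zero-variance estimate sets and < 2 estimates
  are rejected by the t machinery; sites without control plots or with
  non-positive control-mean weeds are unusable for invasibility;
  collinear stability designs (constant richness) raise rather than
  silently dropping terms. Fit non-convergence after the restart
  ladder raises a `FitError` with the start value and n.

## Problem sizes used in validation

The test suite and the acceptance script run on the full seven-site
synthetic design (760 quadrat observations), single-site instances
(120 plots) for fitting properties, 20-point instances against a
brute-force β₁ grid (step 10⁻⁵), and 200 replicate sites for recovery
diagnostics; the complete pipeline runs in a few seconds on one CPU.
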