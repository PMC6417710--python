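# covermix

Statistical analysis of cover crop mixture field trials: does increasing
mixture diversity increase biomass productivity, weed suppression, or
biomass stability?

`covermix` is built for agronomists and ecologists analysing multi-site
randomized complete block (RCBD) cover crop trials in which 18 species —
three from each of six functional groups (cool/warm-season grasses,
legumes, brassicas/broadleaves) — are grown as pure stands and as
substitutive mixtures of up to 18 species. It implements three linked
analyses plus a synthetic trial generator with known ground truth so the
whole pipeline can be validated without field data.

## The three analyses

**Diversity–productivity.** Per-block effect sizes contrast mixture
biomass *B* with the mean biomass of reference treatments,

    effect size (%) = 100 · (B_mix − B̄_ref) / B̄_ref,

in four families: tripling species richness within one functional group
(three-species grass/legume/brassica mixtures vs their pure stands),
tripling species richness at constant functional richness (the
nine-species mixture vs one-of-each-group mixtures), raising functional
richness at constant species richness, and raising both together (the
nine-species mixture vs the nine pure stands). Block-level estimates are
tested against zero with one-sample *t* tests.

**Diversity–invasibility.** Percent weed biomass reduction relative to
each site's no-cover control mean,
BR = 100 · (w̄_control − w) / w̄_control, is related to total cover
biomass *x* (g m⁻²) by nonlinear least squares:

    BR = 100 − 100·exp(β₁x)            (null)
    BR = 100 − 100·exp(β₁x + β₂xR)     (+SR / +FR)

where *R* is the quadrat's realized species or functional richness.
An extra-sum-of-squares *F* test on β₂ asks whether diversity changes
weed suppression beyond its covariance with biomass.

**Diversity–stability.** For each treatment×site, the standard deviation
of biomass across blocks is regressed on the mean through the origin
(`SD ~ 0 + BIOM`, optionally `+ BIOM:SR` or `+ BIOM:FR`). Regressing SD
on the mean — rather than CV on richness — avoids the mechanical
inflation of CV at low biomass; Pearson correlations of CV with richness
and with mean biomass are provided as diagnostics of that confound.

## Worked example

Generate the built-in seven-site synthetic trial (seed 1) and run the
effect-size analysis:

```bash
covermix effects --seed 1 --out out/
```

```
 contrast   n  mean  ci95_low  ci95_high  ci50_low  ci50_high     t         p
       SR 108 6.666     1.689      11.64     4.967      8.365 2.655  0.009144
       FR  27 26.86     18.62      35.11     24.12      29.61 6.697  4.18e-07
SR_and_FR  27 35.19     26.39      43.99     32.26      38.12 8.222 1.054e-08
```

Raising species richness alone (SR, 108 block-level estimates) moves
average biomass by only a few percent, while raising functional richness
(FR) or both together (SR & FR) raises it by roughly 30% — the signature
of low-biomass legumes dragging down low-diversity averages rather than
of niche complementarity. The invasibility table for the same trial:

```bash
covermix invasibility --seed 1 --out out/
```

```
 site model  df  beta1_x1000  beta1_sem_x1000  beta2_x1000  beta2_sem_x1000  rmse   f_value  p_value
    3  Null  79        -54.1            5.247          NaN              NaN 7.508       NaN      NaN
   10  Null 159       -6.374           0.2375          NaN              NaN 12.81       NaN      NaN
   11  Null 119       -5.474           0.2415          NaN              NaN  14.4       NaN      NaN
   ...
```

β₁×10³ is the weed-suppression rate per g m⁻² of cover biomass (site 3's
steep −54 reflects a low-biomass site where every gram counts); the +SR
and +FR rows (elided) test whether richness adds predictive power via
the nested *F* test. `covermix stability` and `covermix report` complete
the pipeline; `covermix simulate` writes the synthetic trial CSV with a
ground-truth sidecar.

The same analyses are available as library objects
(`DiversityEffects(dataset).fit()`, `InvasibilityModel(dataset,
site=10).fit()`, `StabilityModel(records).fit()`), each returning a
results object with estimates, SEMs, p-values and a `summary()` table.
Field data are read from a long-format CSV (one row per site, block,
treatment, quadrat, taxon) via `read_trial_csv`, with a `--column-map`
YAML adapting other headers.

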