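"""Synthetic multi-site RCBD cover crop trial generator.

Generates datasets with the statistical structure the analysis assumes,
with known ground truth, so every downstream stage is testable:

* species-level biomass driven by pure-stand performance, with mixtures
  following a dominance-weighted average of constituent pure-stand
  expectations (no niche-complementarity bonus — deliberately the null
  mechanism, under which a mixture can never out-produce its best
  constituent);
* strong functional-group contrasts (legumes low; grasses and brassicas
  high), which makes functional-richness contrasts positive while
  within-group species-richness contrasts stay near zero;
* weed biomass declining exponentially in total cover biomass with a
  site-specific rate beta1 < 0;
* multiplicative lognormal noise at plot and block level (biomass is
  positive and right-skewed);
* Bernoulli dropout of low-share species from a quadrat, so realized
  richness falls below seeded richness at high seeded richness; the
  surviving species compensate, so a plot's expected total biomass is
  unchanged (dropout is a richness phenomenon, not a biomass loss).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .catalog import Catalog, SiteInfo, TreatmentDefinition, build_catalog
from .io import Dataset, PlotObservation, config_hash

__all__ = [
    "SiteSpec",
    "SyntheticConfig",
    "GroundTruth",
    "default_config",
    "expected_mixture_biomass",
    "generate",
    "legume_drawdown_scenario",
]


@dataclass(frozen=True)
class SiteSpec:
    """One synthetic site: design constants plus generative parameters."""

    site_id: int
    n_blocks: int = 4
    year: int = 2013
    n_quadrats_per_plot: int = 1
    productivity_multiplier: float = 1.0
    weed_sampled: bool = False
    beta1: float | None = None  # overrides SyntheticConfig.beta1_true

    @property
    def treatment_ids(self) -> tuple[int, ...]:
        upper = 40 if self.year == 2014 else 20
        return tuple(range(1, upper + 1))


# Default expected pure-stand biomass (g m^-2), ordered by the trial's
# consistent pattern: grasses and brassicas productive, legumes low;
# sorghum sudangrass and buckwheat dominant among warm-season species.
DEFAULT_SPECIES_MEANS: dict[str, float] = {
    "BAR": 330.0, "OAT": 300.0, "WHT": 270.0,
    "PEA": 80.0, "RED": 50.0, "YEL": 50.0,
    "RAD": 385.0, "RAPE": 350.0, "TURN": 315.0,
    "PROSO": 200.0, "SORG": 400.0, "TEFF": 100.0,
    "CHICK": 90.0, "COW": 110.0, "SUNN": 70.0,
    "BUCK": 300.0, "SAFF": 150.0, "SUNF": 150.0,
}

# Weed-sampled sites use the weed response rates (per g m^-2) the trial
# design targets; sites without weed data share the generic default.
DEFAULT_SITES: tuple[SiteSpec, ...] = (
    SiteSpec(3, 4, 2013, 2, 0.9, weed_sampled=True, beta1=-0.057),
    SiteSpec(4, 4, 2013, 1, 0.25),
    SiteSpec(5, 4, 2013, 1, 0.20),
    SiteSpec(7, 4, 2013, 1, 0.15),
    SiteSpec(8, 4, 2013, 1, 0.12),
    SiteSpec(10, 4, 2014, 1, 1.3, weed_sampled=True, beta1=-0.0069),
    SiteSpec(11, 3, 2014, 1, 1.2, weed_sampled=True, beta1=-0.0068),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic trial.

    Noise magnitudes are coefficients of variation of multiplicative
    lognormal factors with mean 1; the combined plot-to-plot CV of total
    biomass is about one-third under the defaults.
    """

    seed: int = 0
    sites: tuple[SiteSpec, ...] = DEFAULT_SITES
    species_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECIES_MEANS))
    species_cv: float = 0.30
    block_sd: float = 0.15
    gamma: float = 1.0  # dominance weight exponent; 0 = plain mean
    beta1_true: float = -0.0069  # per g m^-2, used where SiteSpec.beta1 is None
    weed_control_mean: float = 100.0  # g m^-2
    weed_cv: float = 0.35
    dropout_base: float = 0.30
    share_threshold: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if self.beta1_true >= 0:
            raise ValueError("beta1_true must be negative")
        if any(m <= 0 for m in self.species_means.values()):
            raise ValueError("species means must be positive")
        for cv in (self.species_cv, self.block_sd, self.weed_cv):
            if cv < 0:
                raise ValueError("noise CVs must be non-negative")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")

    def site_beta1(self, spec: SiteSpec) -> float:
        return self.beta1_true if spec.beta1 is None else spec.beta1


@dataclass
class GroundTruth:
    """Closed-form expectations implied by a config with noise off."""

    expected_biomass: dict[tuple[int, int], float]  # (site, treatment) -> g m^-2
    beta1_true: dict[int, float]  # weed-sampled site -> rate
    expected_effect_sizes: dict[str, float]  # contrast family -> %
    config: SyntheticConfig


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The seven-sampled-site trial emulation with default parameters."""
    return replace(SyntheticConfig(seed=seed), **overrides) if overrides else SyntheticConfig(seed=seed)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def _species_weights(config: SyntheticConfig, codes: list[str]) -> np.ndarray:
    """Dominance weights share_s * c_s with c_s = mu_s^gamma and equal shares."""
    mu = np.array([config.species_means[c] for c in codes])
    return mu**config.gamma


def expected_mixture_biomass(
    config: SyntheticConfig, treatment: TreatmentDefinition, site: SiteSpec | SiteInfo
) -> float:
    """Expected total biomass (g m^-2) of a treatment at a site, noise off.

    Dominance-weighted average of constituent pure-stand expectations:
    ``mult * sum(share*mu*c) / sum(share*c)`` with ``c = mu^gamma`` and
    equal shares 1/richness.  Reduces to ``mult * mu`` for a pure stand
    and never exceeds the largest constituent pure-stand expectation.
    """
    codes = sorted(treatment.species_codes)
    if not codes:
        raise ValueError("control treatment has no expected cover biomass")
    mult = getattr(site, "productivity_multiplier", 1.0)
    mu = np.array([config.species_means[c] for c in codes])
    c = _species_weights(config, codes)
    return float(mult * np.sum(mu * c) / np.sum(c))


def _expected_species_biomass(
    config: SyntheticConfig, treatment: TreatmentDefinition, site: SiteSpec
) -> dict[str, float]:
    """Per-species expected biomass within a plot; sums to the mixture total."""
    codes = sorted(treatment.species_codes)
    total = expected_mixture_biomass(config, treatment, site)
    mu = np.array([config.species_means[c] for c in codes])
    w = mu * _species_weights(config, codes)
    w = w / w.sum()
    return {c: float(total * wi) for c, wi in zip(codes, w)}


def _closed_form_effect_sizes(
    config: SyntheticConfig, catalog: Catalog
) -> dict[str, float]:
    """Contrast-family effect sizes implied by the configured means.

    Site productivity multipliers cancel in every ratio, so the values
    are site-independent; a unit-multiplier site stands in.
    """
    unit = SiteSpec(site_id=0, productivity_multiplier=1.0)

    def e(tid: int) -> float:
        return expected_mixture_biomass(config, catalog.treatment(tid), unit)

    pure_by_mix = {11: (2, 3, 4), 12: (5, 6, 7), 13: (8, 9, 10)}
    sr_within = [
        100.0 * (e(m) - np.mean([e(p) for p in pures])) / np.mean([e(p) for p in pures])
        for m, pures in pure_by_mix.items()
    ]
    b_18_20 = np.mean([e(t) for t in (18, 19, 20)])
    b_11_13 = np.mean([e(t) for t in (11, 12, 13)])
    b_pure = np.mean([e(t) for t in range(2, 11)])
    sr_functional = 100.0 * (e(17) - b_18_20) / b_18_20
    return {
        "sr_within_mean": float(np.mean(sr_within)),
        "sr_functional": float(sr_functional),
        "sr_pooled": float(np.mean(sr_within + [sr_functional])),
        "fr": float(100.0 * (b_18_20 - b_11_13) / b_11_13),
        "sr_fr": float(100.0 * (e(17) - b_pure) / b_pure),
    }


def generate(
    config: SyntheticConfig, catalog: Catalog | None = None
) -> tuple[Dataset, GroundTruth]:
    """Generate one full synthetic trial.

    One observation per site x block x treatment x quadrat.  Fully
    reproducible from ``config.seed``; each site uses an independent
    substream keyed by (seed, site_id), so adding or removing a site
    leaves the others' data unchanged.
    """
    catalog = catalog or build_catalog()
    observations: list[PlotObservation] = []
    expected: dict[tuple[int, int], float] = {}
    beta1_map: dict[int, float] = {}

    for spec in config.sites:
        rng = np.random.default_rng([config.seed, spec.site_id])
        beta1 = config.site_beta1(spec)
        if spec.weed_sampled:
            beta1_map[spec.site_id] = beta1
        block_effects = _lognormal_factors(rng, config.block_sd, spec.n_blocks)

        # per-treatment constants: sorted codes, dominance weights, total
        per_trt: dict[int, tuple[list[str], np.ndarray, float]] = {}
        for tid in spec.treatment_ids:
            trt = catalog.treatment(tid)
            if trt.species_codes:
                codes = sorted(trt.species_codes)
                mu = np.array([config.species_means[c] for c in codes])
                weights = mu ** (1.0 + config.gamma)  # share * mu * c, equal shares
                total = expected_mixture_biomass(config, trt, spec)
                per_trt[tid] = (codes, weights, total)
                expected[(spec.site_id, tid)] = total
            else:
                expected[(spec.site_id, tid)] = 0.0

        for block in range(1, spec.n_blocks + 1):
            for tid in spec.treatment_ids:
                trt = catalog.treatment(tid)
                richness = trt.seeded_species_richness
                share = 1.0 / richness if richness else 0.0
                droppable = (
                    config.dropout_base > 0 and share < config.share_threshold
                )
                for quadrat in range(1, spec.n_quadrats_per_plot + 1):
                    cover: dict[str, float] = {}
                    if tid in per_trt:
                        codes, weights, total = per_trt[tid]
                        keep = np.ones(len(codes), dtype=bool)
                        if droppable:
                            keep = rng.random(len(codes)) >= config.dropout_base
                        if keep.any():
                            # survivors compensate: plot expectation stays at
                            # the mixture total, shares renormalized over the
                            # species actually present in the quadrat
                            w = weights[keep]
                            e_sp = total * w / w.sum()
                            noise = _lognormal_factors(rng, config.species_cv, int(keep.sum()))
                            vals = e_sp * block_effects[block - 1] * np.atleast_1d(noise)
                            cover = {
                                c: float(v)
                                for c, v in zip(np.array(codes)[keep], vals)
                            }
                    weed: dict[str, float] = {}
                    if spec.weed_sampled:
                        x = sum(cover.values())
                        w = (
                            config.weed_control_mean
                            * math.exp(beta1 * x)
                            * float(_lognormal_factors(rng, config.weed_cv, None))
                        )
                        # fixed split across two genera keeps the total exact
                        weed = {"Amaranthus spp.": 0.6 * w, "Setaria spp.": 0.4 * w}
                    observations.append(
                        PlotObservation(spec.site_id, block, tid, quadrat, cover, weed)
                    )

    truth = GroundTruth(
        expected_biomass=expected,
        beta1_true=beta1_map,
        expected_effect_sizes=_closed_form_effect_sizes(config, catalog),
        config=config,
    )
    return Dataset(observations, provenance=f"synthetic:{config_hash(config)}"), truth


def legume_drawdown_scenario(config: SyntheticConfig | None = None) -> SyntheticConfig:
    """Config variant isolating the low-legume-biomass mechanism.

    Within each functional group, species means are equalized at the
    group mean (so within-group species-richness contrasts are exactly
    zero with noise off), and legume means are set to 20% of the mean of
    the same season's grass and brassica/broadleaf groups (so the
    functional-richness contrast is strictly positive).
    """
    config = config or SyntheticConfig()
    catalog = build_catalog()
    groups: dict[str, list[str]] = {}
    for sp in catalog.species:
        groups.setdefault(sp.functional_group, []).append(sp.code)

    means = dict(config.species_means)
    group_mean = {g: float(np.mean([means[c] for c in codes])) for g, codes in groups.items()}
    for g, codes in groups.items():
        for c in codes:
            means[c] = group_mean[g]
    for legume_g, others in (("CL", ("CG", "CB")), ("WL", ("WG", "WB"))):
        target = 0.2 * float(np.mean([group_mean[g] for g in others]))
        for c in groups[legume_g]:
            means[c] = target
    return replace(config, species_means=means)
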