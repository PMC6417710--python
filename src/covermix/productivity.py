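"""Effect-size contrasts for the diversity-productivity question.

Four contrast families compare mixture biomass with the mean of
reference treatments, per block within each site, each expressed as a
percentage of the reference:

* ``SR_within_group`` — each three-species single-group mixture
  (treatments 11, 12, 13) against the mean of its constituent pure
  stands: species richness tripled within one functional group.
* ``SR_functional`` — the nine-species mixture (17) against the mean of
  the three one-of-each-group mixtures (18-20): species richness tripled
  at constant functional richness three.
* ``FR`` — mean of treatments 18-20 against mean of 11-13: functional
  richness raised from one to three at constant species richness.
* ``SR_and_FR`` — treatment 17 against the mean of the nine pure stands
  (2-10): both raised together.

The pooled ``SR`` family concatenates the two species-richness families
with equal weight.  Per-block estimates are treated as independent and
tested against zero with one-sample t-tests.  Warm-season treatments
(21-40) are excluded from all contrasts; their summary means are still
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import Catalog, build_catalog
from .io import Dataset, aggregate_quadrats, total_cover_biomass

__all__ = [
    "EffectSizeSummary",
    "DiversityEffects",
    "EffectSizeResults",
    "block_biomass",
    "effect_size_sr_within",
    "effect_size_sr_functional",
    "effect_size_fr",
    "effect_size_sr_fr",
    "one_sample_t",
    "treatment_site_means",
]

_PURE_BY_MIX = {11: (2, 3, 4), 12: (5, 6, 7), 13: (8, 9, 10)}


def _biomass_lookup(ds: Dataset) -> dict[tuple[int, int, int], float]:
    ds = aggregate_quadrats(ds)
    return {o.plot_key: total_cover_biomass(o) for o in ds.observations}


def block_biomass(ds: Dataset, site: int, block: int, treatment: int) -> float | None:
    """Total cover biomass of one plot (quadrats averaged), or None if absent."""
    return _biomass_lookup(ds).get((site, block, treatment))


def _site_blocks(lookup: dict[tuple[int, int, int], float]) -> list[tuple[int, int]]:
    return sorted({(s, b) for (s, b, _t) in lookup})


def _mean_of(lookup, site, block, treatments) -> float | None:
    vals = [lookup.get((site, block, t)) for t in treatments]
    if any(v is None for v in vals):
        return None
    return float(np.mean(vals))


def _pct(mix: float | None, ref: float | None) -> float | None:
    if mix is None or ref is None or ref == 0:
        return None
    return 100.0 * (mix - ref) / ref


def _contrast_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["site", "block", "label", "estimate"])


def effect_size_sr_within(ds: Dataset, catalog: Catalog | None = None) -> pd.DataFrame:
    """Per-block estimates: single-group mixtures vs their pure stands.

    Three estimates per site x block (grass, legume, brassica mixtures);
    an estimate is missing if any component plot is missing.
    """
    lookup = _biomass_lookup(ds)
    rows = []
    for site, block in _site_blocks(lookup):
        for mix, pures in _PURE_BY_MIX.items():
            est = _pct(lookup.get((site, block, mix)), _mean_of(lookup, site, block, pures))
            if est is not None:
                rows.append({"site": site, "block": block, "label": f"mix{mix}", "estimate": est})
    return _contrast_frame(rows)


def effect_size_sr_functional(ds: Dataset, catalog: Catalog | None = None) -> pd.DataFrame:
    """Per-block estimates: nine-species mixture vs mean of treatments 18-20."""
    lookup = _biomass_lookup(ds)
    rows = []
    for site, block in _site_blocks(lookup):
        est = _pct(lookup.get((site, block, 17)), _mean_of(lookup, site, block, (18, 19, 20)))
        if est is not None:
            rows.append({"site": site, "block": block, "label": "t17_vs_18_20", "estimate": est})
    return _contrast_frame(rows)


def effect_size_fr(ds: Dataset, catalog: Catalog | None = None) -> pd.DataFrame:
    """Per-block estimates: mean of 18-20 vs mean of 11-13 (functional richness)."""
    lookup = _biomass_lookup(ds)
    rows = []
    for site, block in _site_blocks(lookup):
        est = _pct(
            _mean_of(lookup, site, block, (18, 19, 20)),
            _mean_of(lookup, site, block, (11, 12, 13)),
        )
        if est is not None:
            rows.append({"site": site, "block": block, "label": "fr", "estimate": est})
    return _contrast_frame(rows)


def effect_size_sr_fr(ds: Dataset, catalog: Catalog | None = None) -> pd.DataFrame:
    """Per-block estimates: treatment 17 vs mean of the nine pure stands."""
    lookup = _biomass_lookup(ds)
    rows = []
    for site, block in _site_blocks(lookup):
        est = _pct(lookup.get((site, block, 17)), _mean_of(lookup, site, block, range(2, 11)))
        if est is not None:
            rows.append({"site": site, "block": block, "label": "sr_fr", "estimate": est})
    return _contrast_frame(rows)


@dataclass
class EffectSizeSummary:
    """One-sample t inference for one contrast family."""

    contrast: str
    estimates: list[float]
    n: int
    mean: float
    ci95: tuple[float, float]
    ci50: tuple[float, float]
    t_stat: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "n": self.n,
            "mean": self.mean,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "ci50_low": self.ci50[0],
            "ci50_high": self.ci50[1],
            "t": self.t_stat,
            "p": self.p_value,
        }


def one_sample_t(estimates, contrast: str = "") -> EffectSizeSummary:
    """Two-sided one-sample t-test of H0: mean effect = 0, with t CIs.

    Raises ``ValueError`` for fewer than two estimates or zero variance.
    """
    x = np.asarray(list(estimates), dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("one_sample_t requires at least two estimates")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("one_sample_t requires nonzero variance")
    mean = float(x.mean())
    se = sd / math.sqrt(n)
    t_stat = mean / se
    p = 2.0 * stats.t.sf(abs(t_stat), df=n - 1)

    def ci(level: float) -> tuple[float, float]:
        q = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
        return (mean - q * se, mean + q * se)

    return EffectSizeSummary(contrast, x.tolist(), n, mean, ci(0.95), ci(0.50), float(t_stat), float(p))


def treatment_site_means(ds: Dataset, catalog: Catalog | None = None) -> pd.DataFrame:
    """Mean total cover biomass per treatment x site (all treatments, incl. warm)."""
    lookup = _biomass_lookup(ds)
    df = pd.DataFrame(
        [{"site": s, "treatment": t, "biomass": v} for (s, b, t), v in lookup.items()]
    )
    return (
        df.groupby(["site", "treatment"], as_index=False)["biomass"]
        .agg(mean_biomass="mean", n_plots="count")
    )


class DiversityEffects:
    """Effect-size analysis of a trial dataset.

    Parameters
    ----------
    dataset
        Quadrat- or plot-level observations; quadrats are averaged per
        plot before any contrast is formed.
    catalog
        Treatment catalog; defaults to the built-in design.
    """

    def __init__(self, dataset: Dataset, catalog: Catalog | None = None):
        self.catalog = catalog or build_catalog()
        self.dataset = aggregate_quadrats(dataset)

    def fit(self) -> "EffectSizeResults":
        """Compute all per-block estimates and their t inference."""
        within = effect_size_sr_within(self.dataset, self.catalog)
        functional = effect_size_sr_functional(self.dataset, self.catalog)
        fr = effect_size_fr(self.dataset, self.catalog)
        sr_fr = effect_size_sr_fr(self.dataset, self.catalog)
        estimates = {
            "SR_within_group": within,
            "SR_functional": functional,
            "SR": pd.concat([within, functional], ignore_index=True),
            "FR": fr,
            "SR_and_FR": sr_fr,
        }
        summaries = {
            name: one_sample_t(frame["estimate"], contrast=name)
            for name, frame in estimates.items()
            if len(frame) >= 2 and frame["estimate"].std(ddof=1) > 0
        }
        return EffectSizeResults(self, estimates, summaries)


class EffectSizeResults:
    """Per-block effect-size estimates plus one-sample t summaries."""

    #: Families reported in the headline figure-style summary.
    REPORT_FAMILIES = ("SR", "FR", "SR_and_FR")

    def __init__(
        self,
        model: DiversityEffects,
        estimates: dict[str, pd.DataFrame],
        summaries: dict[str, EffectSizeSummary],
    ):
        self.model = model
        self.estimates = estimates
        self.summaries = summaries

    def summary(self, families=None) -> pd.DataFrame:
        """Tidy summary table: mean, CIs, t, p, n per contrast family."""
        families = families or self.REPORT_FAMILIES
        rows = [self.summaries[f].as_dict() for f in families if f in self.summaries]
        return pd.DataFrame(rows)

    def estimates_frame(self) -> pd.DataFrame:
        """All per-block estimates in one tidy frame."""
        frames = []
        for name, frame in self.estimates.items():
            if name == "SR":
                continue  # pooled family duplicates its components
            f = frame.copy()
            f.insert(0, "contrast", name)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def __repr__(self) -> str:
        parts = [
            f"{name}: mean={s.mean:.1f}% (n={s.n}, p={s.p_value:.3g})"
            for name, s in self.summaries.items()
            if name in self.REPORT_FAMILIES
        ]
        return "<EffectSizeResults " + "; ".join(parts) + ">"
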