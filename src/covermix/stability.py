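"""Biomass stability analysis: mean-SD regression and CV diagnostics.

Stability is assessed as plot-to-plot variability within a site: for
each non-control treatment at each site, the sample mean and sample
standard deviation of total cover biomass across blocks.  The SD is
regressed on the mean through the origin, optionally with a
mean x richness interaction:

    SD ~ 0 + BIOM
    SD ~ 0 + BIOM + BIOM:SR
    SD ~ 0 + BIOM + BIOM:FR

A negative interaction slope would indicate that diversity reduces
variability per unit biomass.  The coefficient of variation CV = SD/mean
is also computed, with Pearson correlations of CV against richness and
mean biomass as diagnostics of the productivity confound: regressing CV
directly on diversity is misleading because CV shrinks mechanically as
mean biomass grows.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .catalog import Catalog, build_catalog
from .io import Dataset, aggregate_quadrats, total_cover_biomass
from .richness import realized_richness

logger = logging.getLogger(__name__)

__all__ = [
    "treatment_site_summary",
    "StabilityModel",
    "StabilityResults",
    "cv_diagnostics",
]

CONTROL_TREATMENT = 1


def treatment_site_summary(
    ds: Dataset, catalog: Catalog | None = None, threshold: float = 0.0
) -> pd.DataFrame:
    """Per treatment x site biomass mean, SD (n-1), CV, and richness.

    Control plots are excluded (their biomass is identically zero);
    treatment x site cells with fewer than two plots are dropped with a
    warning.  Quadrats are averaged per plot first.
    """
    catalog = catalog or build_catalog()
    plots = [
        o for o in aggregate_quadrats(ds).observations
        if o.treatment_id != CONTROL_TREATMENT
    ]
    groups: dict[tuple[int, int], list] = {}
    for o in plots:
        groups.setdefault((o.site_id, o.treatment_id), []).append(o)

    rows = []
    for (site, trt), obs in sorted(groups.items()):
        if len(obs) < 2:
            logger.warning(
                "treatment_site_summary: dropping site %d treatment %d (<2 plots)", site, trt
            )
            continue
        biomass = np.array([total_cover_biomass(o) for o in obs])
        sr, fr = catalog.seeded_richness(trt)
        mean = float(biomass.mean())
        sd = float(biomass.std(ddof=1))
        rows.append(
            {
                "site": site,
                "treatment": trt,
                "mean_biomass": mean,
                "sd_biomass": sd,
                "cv": sd / mean if mean > 0 else np.nan,
                "n_plots": len(obs),
                "seeded_sr": sr,
                "seeded_fr": fr,
                "mean_realized_sr": float(
                    np.mean([realized_richness(o, catalog, "species", threshold) for o in obs])
                ),
                "mean_realized_fr": float(
                    np.mean([realized_richness(o, catalog, "functional", threshold) for o in obs])
                ),
            }
        )
    return pd.DataFrame(rows)


class StabilityModel:
    """Zero-intercept SD-vs-mean regression, optionally with richness.

    Parameters
    ----------
    records
        Output of :func:`treatment_site_summary` (or any frame with
        ``mean_biomass``, ``sd_biomass`` and richness columns).
    interaction
        ``None`` for the base model, ``"SR"`` or ``"FR"`` to add a
        mean x richness interaction term.
    richness
        ``"seeded"`` (default; the stability hypothesis concerns the
        insurance value of what was sown) or ``"realized"``.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        interaction: str | None = None,
        richness: str = "seeded",
    ):
        if interaction not in (None, "SR", "FR"):
            raise ValueError("interaction must be None, 'SR' or 'FR'")
        if richness not in ("seeded", "realized"):
            raise ValueError("richness must be 'seeded' or 'realized'")
        self.records = records.reset_index(drop=True)
        self.interaction = interaction
        self.richness = richness
        n_params = 1 if interaction is None else 2
        if len(self.records) < n_params + 1:
            raise ValueError("not enough records for the requested model")

    def _richness_values(self) -> np.ndarray:
        level = self.interaction.lower() if self.interaction else ""
        col = f"seeded_{level}" if self.richness == "seeded" else f"mean_realized_{level}"
        return self.records[col].to_numpy(float)

    def fit(self) -> "StabilityResults":
        m = self.records["mean_biomass"].to_numpy(float)
        sd = self.records["sd_biomass"].to_numpy(float)
        names = ["BIOM"]
        X = m[:, None]
        if self.interaction is not None:
            X = np.column_stack([m, m * self._richness_values()])
            names.append(f"BIOM:{self.interaction}")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("degenerate (collinear) design for SD~mean regression")
        res = sm.OLS(sd, pd.DataFrame(X, columns=names)).fit()
        return StabilityResults(self, res)


class StabilityResults:
    """Zero-intercept regression estimates with SEMs and p-values."""

    def __init__(self, model: StabilityModel, ols_results):
        self.model = model
        self._res = ols_results

    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues

    @property
    def df(self) -> int:
        return int(self._res.df_resid)

    @property
    def slope(self) -> float:
        """The BIOM (SD per unit mean biomass) slope."""
        return float(self.params["BIOM"])

    def summary(self) -> pd.DataFrame:
        label = "SD ~ BIOM" + (
            f" + BIOM:{self.model.interaction}" if self.model.interaction else " (Base model)"
        )
        return pd.DataFrame(
            {
                "equation": label,
                "df": self.df,
                "parameter": self.params.index,
                "estimate": self.params.values,
                "sem": self.bse.values,
                "p_value": self.pvalues.values,
            }
        )

    def __repr__(self) -> str:
        terms = ", ".join(f"{k}={v:.3g}" for k, v in self.params.items())
        return f"<StabilityResults df={self.df} {terms}>"


def cv_diagnostics(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of CV with richness and mean biomass.

    One row per covariate (mean realized species richness, mean realized
    functional richness, mean biomass) with r and its two-sided p-value.
    Raises ``ValueError`` when CV (or a covariate) has no variance.
    """
    recs = records.dropna(subset=["cv"])
    if len(recs) < 3:
        raise ValueError("cv_diagnostics requires at least 3 records with defined CV")
    cv = recs["cv"].to_numpy(float)
    if np.ptp(cv) == 0:
        raise ValueError("CV is constant; correlation undefined")
    rows = []
    for label, col in (
        ("realized_sr", "mean_realized_sr"),
        ("realized_fr", "mean_realized_fr"),
        ("mean_biomass", "mean_biomass"),
    ):
        x = recs[col].to_numpy(float)
        if np.ptp(x) == 0:
            raise ValueError(f"covariate {col} is constant; correlation undefined")
        r, p = stats.pearsonr(cv, x)
        rows.append({"covariate": label, "r": float(r), "p_value": float(p), "n": len(recs)})
    return pd.DataFrame(rows)
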