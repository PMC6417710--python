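"""Exponential weed-suppression model with diversity modifiers.

Percent weed biomass reduction relative to a site's no-cover control
mean, BR = 100 * (w_control_mean - w) / w_control_mean, is related to
total cover crop biomass x (g m^-2) by

    BR = 100 - 100 * exp(beta1 * x)                       (null model)
    BR = 100 - 100 * exp(beta1 * x + beta2 * x * R)       (+SR / +FR)

where R is the quadrat's species or functional richness and beta1 < 0
measures how responsive weed biomass is to cover biomass.  A nested
extra-sum-of-squares F-test on beta2 asks whether diversity changes the
suppression-per-unit-biomass relationship.  Fits are per site and
include every sampled plot, controls entering at x = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .catalog import Catalog, build_catalog
from .io import Dataset, aggregate_quadrats, total_cover_biomass, total_weed_biomass
from .richness import realized_richness

__all__ = [
    "control_mean_weeds",
    "weed_biomass_reduction",
    "invasibility_observations",
    "InvasibilityModel",
    "InvasibilityResults",
    "NestedFResult",
    "nested_f_test",
    "fit_site_models",
]

VARIANTS = ("null", "plus_SR", "plus_FR")

CONTROL_TREATMENT = 1


class FitError(RuntimeError):
    """Nonlinear fit failed to converge after the restart ladder."""


def control_mean_weeds(ds: Dataset, site: int) -> float:
    """Mean total weed biomass (g m^-2) over a site's no-cover control plots."""
    plots = [
        o for o in aggregate_quadrats(ds).observations
        if o.site_id == site and o.treatment_id == CONTROL_TREATMENT
    ]
    if not plots:
        raise ValueError(f"site {site} has no control (treatment 1) observations")
    return float(np.mean([total_weed_biomass(o) for o in plots]))


def weed_biomass_reduction(w: float, w_control_mean: float) -> float:
    """Percent weed biomass reduction relative to the control mean.

    100 for complete suppression, 0 at the control mean; negative values
    (weedier than control) are legal.
    """
    if w_control_mean <= 0:
        raise ValueError(
            "control mean weed biomass must be positive for BR to be defined"
        )
    return 100.0 * (w_control_mean - w) / w_control_mean


def invasibility_observations(
    ds: Dataset,
    site: int,
    catalog: Catalog | None = None,
    threshold: float = 0.0,
    control_mean: float | None = None,
) -> pd.DataFrame:
    """Per-plot model inputs for one site: x, BR, and richness covariates.

    Quadrats are averaged per plot first; every sampled plot of the site
    enters, control plots with x = 0.  ``control_mean`` overrides the
    within-site control-plot estimate of mean weed biomass — useful on
    synthetic data where the generating value is known, since the 3-4
    control plots make the estimated normalizer a noticeable source of
    site-wide correlated error.
    """
    catalog = catalog or build_catalog()
    plots = [o for o in aggregate_quadrats(ds).observations if o.site_id == site]
    if not plots:
        raise ValueError(f"no observations for site {site}")
    w_bar = control_mean if control_mean is not None else control_mean_weeds(ds, site)
    rows = []
    for o in plots:
        sr, fr = catalog.seeded_richness(o.treatment_id)
        rows.append(
            {
                "site": o.site_id,
                "block": o.block,
                "treatment": o.treatment_id,
                "x": total_cover_biomass(o),
                "br": weed_biomass_reduction(total_weed_biomass(o), w_bar),
                "realized_sr": realized_richness(o, catalog, "species", threshold),
                "realized_fr": realized_richness(o, catalog, "functional", threshold),
                "seeded_sr": sr,
                "seeded_fr": fr,
            }
        )
    return pd.DataFrame(rows)


def _model_z(params: np.ndarray, x: np.ndarray, xr: np.ndarray | None) -> np.ndarray:
    z = params[0] * x
    if xr is not None:
        z = z + params[1] * xr
    return z


def _predict(params: np.ndarray, x: np.ndarray, xr: np.ndarray | None) -> np.ndarray:
    # clip the exponent so wild parameter values explored during
    # optimization stay finite; irrelevant at any sane optimum
    z = np.clip(_model_z(params, x, xr), None, 500.0)
    return 100.0 - 100.0 * np.exp(z)


def _initial_beta1(x: np.ndarray, br: np.ndarray, eps: float = 1e-6) -> float:
    """Zero-intercept log-linear start: ln(1 - BR/100) = beta1 * x.

    Uses only points below 99% reduction (where the log is informative)
    with positive x; falls back to a mild default slope when degenerate.
    """
    mask = (br < 99.0) & (x > 0)
    if mask.sum() >= 2:
        y = np.log(np.maximum(eps, 1.0 - br[mask] / 100.0))
        denom = float(np.sum(x[mask] ** 2))
        if denom > 0:
            b = float(np.sum(y * x[mask]) / denom)
            if b < 0:
                return b
    return -0.01


def _fit_nls(
    x: np.ndarray, br: np.ndarray, xr: np.ndarray | None
) -> tuple[np.ndarray, float]:
    """Least-squares fit with a restart ladder over the beta1 start value."""
    n_params = 1 if xr is None else 2
    b1 = _initial_beta1(x, br)

    def residuals(p):
        return br - _predict(p, x, xr)

    def jac(p):
        e = 100.0 * np.exp(_model_z(p, x, xr))
        cols = [e * x]
        if xr is not None:
            cols.append(e * xr)
        return np.column_stack(cols)

    best: tuple[np.ndarray, float] | None = None
    for scale in (1.0, 0.5, 2.0):
        p0 = np.zeros(n_params)
        p0[0] = b1 * scale
        try:
            sol = optimize.least_squares(residuals, p0, jac=jac, method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if not sol.success:
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[1] - 1e-12:
            best = (sol.x, sse)
    if best is None:
        raise FitError(
            f"exponential fit failed to converge (n={x.size}, beta1 start {b1:.4g})"
        )
    return best


@dataclass
class NestedFResult:
    """Extra-sum-of-squares F-test between nested fits."""

    f_value: float
    p_value: float
    df_num: int
    df_den: int


def nested_f_test(fit_null: "InvasibilityResults", fit_ext: "InvasibilityResults") -> NestedFResult:
    """F = ((SSE0 - SSE1)/1) / (SSE1/df1), p from F(1, df1) upper tail."""
    if fit_ext.nobs != fit_null.nobs:
        raise ValueError("nested F-test requires fits on the same observations")
    if fit_ext.df != fit_null.df - 1:
        raise ValueError("extended fit must have exactly one extra parameter")
    df_num = fit_null.df - fit_ext.df
    f = ((fit_null.sse - fit_ext.sse) / df_num) / (fit_ext.sse / fit_ext.df)
    f = max(f, 0.0)  # guard tiny negative values from convergence noise
    p = float(stats.f.sf(f, df_num, fit_ext.df))
    return NestedFResult(float(f), p, df_num, fit_ext.df)


class InvasibilityModel:
    """Exponential weed-suppression model for one site.

    Parameters
    ----------
    data
        Either a :class:`Dataset` (with ``site`` given) or a prepared
        frame from :func:`invasibility_observations`.
    variant
        ``"null"``, ``"plus_SR"`` (richness modifier = species richness)
        or ``"plus_FR"`` (functional richness).
    richness
        ``"realized"`` (default; a seeded-but-absent species cannot
        suppress weeds in the quadrat) or ``"seeded"``.
    """

    def __init__(
        self,
        data: Dataset | pd.DataFrame,
        site: int | None = None,
        variant: str = "null",
        richness: str = "realized",
        catalog: Catalog | None = None,
        threshold: float = 0.0,
        control_mean: float | None = None,
    ):
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if richness not in ("realized", "seeded"):
            raise ValueError("richness must be 'realized' or 'seeded'")
        if isinstance(data, Dataset):
            if site is None:
                raise ValueError("site is required when passing a Dataset")
            data = invasibility_observations(data, site, catalog, threshold, control_mean)
        self.data = data.reset_index(drop=True)
        self.site = site if site is not None else int(self.data["site"].iloc[0])
        self.variant = variant
        self.richness = richness
        if len(self.data) < 5:
            raise ValueError("invasibility fit requires at least 5 observations")

    @property
    def _r_column(self) -> str | None:
        if self.variant == "null":
            return None
        level = "sr" if self.variant == "plus_SR" else "fr"
        return f"{self.richness}_{level}"

    def fit(self) -> "InvasibilityResults":
        x = self.data["x"].to_numpy(float)
        br = self.data["br"].to_numpy(float)
        rcol = self._r_column
        xr = x * self.data[rcol].to_numpy(float) if rcol else None
        params, sse = _fit_nls(x, br, xr)
        n = x.size
        df = n - params.size
        sigma2 = sse / df if df > 0 else np.nan
        # Jacobian of the prediction wrt (beta1[, beta2]) at the optimum
        jac = 100.0 * np.exp(_model_z(params, x, xr))
        J = np.column_stack([jac * x] + ([jac * xr] if xr is not None else []))
        try:
            cov = sigma2 * np.linalg.inv(J.T @ J)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            bse = np.full(params.size, np.nan)
        return InvasibilityResults(self, params, bse, sse, df, n)


class InvasibilityResults:
    """Fitted parameters, SEMs, fit diagnostics, and model comparison."""

    def __init__(self, model, params, bse, sse, df, nobs):
        self.model = model
        self.params = np.asarray(params, float)
        self.bse = np.asarray(bse, float)
        self.sse = float(sse)
        self.df = int(df)
        self.nobs = int(nobs)

    @property
    def beta1(self) -> float:
        return float(self.params[0])

    @property
    def beta2(self) -> float | None:
        return float(self.params[1]) if self.params.size > 1 else None

    @property
    def rmse(self) -> float:
        """Root mean squared error on the BR (%) scale, SSE/df based."""
        return float(np.sqrt(self.sse / self.df))

    def predict(self, x, r=None) -> np.ndarray:
        x = np.asarray(x, float)
        if self.model.variant == "null":
            xr = None
        else:
            if r is None:
                raise ValueError("extended model prediction needs richness values")
            xr = x * np.asarray(r, float)
        return _predict(self.params, x, xr)

    def pvalues(self) -> np.ndarray:
        """Two-sided t p-values for each parameter against zero."""
        t = self.params / self.bse
        return 2.0 * stats.t.sf(np.abs(t), df=self.df)

    def compare_f_test(self, restricted: "InvasibilityResults") -> NestedFResult:
        return nested_f_test(restricted, self)

    def summary(self) -> pd.DataFrame:
        """Parameter table with estimates and SEMs scaled x 1000."""
        names = ["beta1"] + (["beta2"] if self.params.size > 1 else [])
        return pd.DataFrame(
            {
                "parameter": names,
                "estimate_x1000": self.params * 1e3,
                "sem_x1000": self.bse * 1e3,
                "p_value": self.pvalues(),
            }
        ).assign(site=self.model.site, variant=self.model.variant, df=self.df, rmse=self.rmse)

    def __repr__(self) -> str:
        b2 = f", beta2*1e3={self.beta2 * 1e3:.2g}" if self.beta2 is not None else ""
        return (
            f"<InvasibilityResults site={self.model.site} {self.model.variant}: "
            f"beta1*1e3={self.beta1 * 1e3:.3g}{b2}, df={self.df}, rmse={self.rmse:.1f}>"
        )


def fit_site_models(
    ds: Dataset,
    catalog: Catalog | None = None,
    richness: str = "realized",
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-site fits of all three variants with nested F-tests.

    Returns a table with one row per site x variant: df, beta1 and beta2
    (x 1000, with SEMs), RMSE, and the F-test of the variant against the
    site's null fit.  Sites without weed data (no weed biomass anywhere,
    or no usable control mean) are skipped.
    """
    catalog = catalog or build_catalog()
    rows = []
    for site in ds.site_ids:
        site_obs = [o for o in ds.for_site(site)]
        if not any(o.weed_biomass_by_taxon for o in site_obs):
            continue
        try:
            frame = invasibility_observations(ds, site, catalog, threshold)
        except ValueError:
            continue
        fits: dict[str, InvasibilityResults] = {}
        for variant in VARIANTS:
            fits[variant] = InvasibilityModel(
                frame, site=site, variant=variant, richness=richness
            ).fit()
        null = fits["null"]
        for variant in VARIANTS:
            res = fits[variant]
            ftest = nested_f_test(null, res) if variant != "null" else None
            rows.append(
                {
                    "site": site,
                    "model": {"null": "Null", "plus_SR": "+ SR", "plus_FR": "+ FR"}[variant],
                    "df": res.df,
                    "beta1_x1000": res.beta1 * 1e3,
                    "beta1_sem_x1000": res.bse[0] * 1e3,
                    "beta2_x1000": (res.beta2 * 1e3) if res.beta2 is not None else np.nan,
                    "beta2_sem_x1000": (res.bse[1] * 1e3) if res.params.size > 1 else np.nan,
                    "rmse": res.rmse,
                    "f_value": ftest.f_value if ftest else np.nan,
                    "p_value": ftest.p_value if ftest else np.nan,
                }
            )
    return pd.DataFrame(rows)
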