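"""Exponential weed-suppression fits, SEMs, and nested F-tests."""

import numpy as np
import pandas as pd
import pytest

import covermix as cm
from covermix.invasibility import (
    InvasibilityModel,
    InvasibilityResults,
    control_mean_weeds,
    fit_site_models,
    invasibility_observations,
    nested_f_test,
    weed_biomass_reduction,
)
from covermix.io import Dataset, PlotObservation


def _frame(x, br, sr=None, fr=None):
    n = len(x)
    return pd.DataFrame(
        {
            "site": 1, "block": 1, "treatment": np.arange(n),
            "x": x, "br": br,
            "realized_sr": sr if sr is not None else np.ones(n),
            "realized_fr": fr if fr is not None else np.ones(n),
            "seeded_sr": sr if sr is not None else np.ones(n),
            "seeded_fr": fr if fr is not None else np.ones(n),
        }
    )


class TestBRweed:
    def test_complete_suppression(self):
        assert weed_biomass_reduction(0.0, 60.0) == 100.0

    def test_at_control_mean(self):
        assert weed_biomass_reduction(60.0, 60.0) == 0.0

    def test_negative_br_is_legal(self):
        assert weed_biomass_reduction(120.0, 60.0) == -100.0

    def test_nonpositive_control_errors(self):
        with pytest.raises(ValueError):
            weed_biomass_reduction(10.0, 0.0)

    def test_control_mean_weeds(self):
        ds = Dataset(
            [
                PlotObservation(3, 1, 1, 1, {}, {"w": 50.0}),
                PlotObservation(3, 2, 1, 1, {}, {"w": 70.0}),
                PlotObservation(3, 1, 2, 1, {"BAR": 10.0}, {"w": 5.0}),
            ]
        )
        assert control_mean_weeds(ds, 3) == pytest.approx(60.0)
        with pytest.raises(ValueError, match="no control"):
            control_mean_weeds(ds, 4)


class TestFitting:
    def test_noise_free_recovery_to_six_decimals(self, noise_free_trial):
        ds, truth = noise_free_trial
        for site, b1 in truth.beta1_true.items():
            res = InvasibilityModel(ds, site=site).fit()
            assert res.beta1 == pytest.approx(b1, abs=1e-9)
            assert res.sse == pytest.approx(0.0, abs=1e-12)

    def test_exact_two_parameter_recovery(self):
        """A dataset generated exactly from the extended model is recovered."""
        rng = np.random.default_rng(0)
        x = np.linspace(0, 800, 40)
        r = rng.integers(1, 10, size=40)
        b1, b2 = -0.004, -0.0008
        br = 100 - 100 * np.exp(b1 * x + b2 * x * r)
        res = InvasibilityModel(_frame(x, br, sr=r), variant="plus_SR").fit()
        assert res.beta1 == pytest.approx(b1, abs=1e-10)
        assert res.beta2 == pytest.approx(b2, abs=1e-10)

    def test_grid_search_oracle_equivalence(self, single_weed_site_config):
        """Brute-force SSE minimum matches the solver within 1e-6 relative."""
        cfg = single_weed_site_config(123)
        ds, _ = cm.generate(cfg)
        frame = invasibility_observations(ds, 11).head(20)
        res = InvasibilityModel(frame).fit()
        x = frame["x"].to_numpy()
        br = frame["br"].to_numpy()
        grid = np.arange(-0.2, 0.0, 1e-5)
        sse = ((br[None, :] - (100 - 100 * np.exp(grid[:, None] * x[None, :]))) ** 2).sum(axis=1)
        assert res.sse <= sse.min() * (1 + 1e-6)
        assert res.beta1 == pytest.approx(grid[sse.argmin()], abs=2e-5)

    def test_model_anchored_at_origin_and_bounded(self):
        x = np.linspace(0, 600, 30)
        br = 100 - 100 * np.exp(-0.01 * x)
        res = InvasibilityModel(_frame(x, br)).fit()
        pred = res.predict(np.linspace(0, 2000, 50))
        assert pred[0] == pytest.approx(0.0)
        assert (pred <= 100.0).all()

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            InvasibilityModel(_frame([0, 1, 2], [0, 1, 2]))

    def test_df_bookkeeping_matches_design(self, default_trial):
        """Null-model df per site: 79 (site 3), 159 (site 10), 119 (site 11)."""
        ds, _ = default_trial
        table = fit_site_models(ds)
        null = table[table["model"] == "Null"].set_index("site")
        assert null.loc[3, "df"] == 79
        assert null.loc[10, "df"] == 159
        assert null.loc[11, "df"] == 119
        ext = table[table["model"] != "Null"]
        assert (ext.groupby("site")["df"].unique().apply(lambda u: u[0]) == null["df"] - 1).all()

    def test_sem_scaling_in_summary(self, default_trial):
        ds, _ = default_trial
        res = InvasibilityModel(ds, site=10).fit()
        summ = res.summary()
        assert summ.loc[0, "estimate_x1000"] == pytest.approx(res.beta1 * 1e3)
        assert res.rmse == pytest.approx(np.sqrt(res.sse / res.df))


class TestNestedF:
    def test_equal_sse_gives_f_zero(self):
        m = InvasibilityModel(_frame(np.linspace(0, 100, 12), np.zeros(12)))
        a = InvasibilityResults(m, [-0.01], [0.1], sse=50.0, df=10, nobs=11)
        b = InvasibilityResults(m, [-0.01, 0.0], [0.1, 0.1], sse=50.0, df=9, nobs=11)
        res = nested_f_test(a, b)
        assert res.f_value == 0.0
        assert res.p_value == 1.0

    def test_hand_arithmetic(self):
        m = InvasibilityModel(_frame(np.linspace(0, 100, 12), np.zeros(12)))
        a = InvasibilityResults(m, [-0.01], [0.1], sse=100.0, df=10, nobs=11)
        b = InvasibilityResults(m, [-0.01, 0.0], [0.1, 0.1], sse=80.0, df=9, nobs=11)
        res = nested_f_test(a, b)
        assert res.f_value == pytest.approx(20.0 / (80.0 / 9.0))
        assert res.df_num == 1 and res.df_den == 9

    def test_mismatched_fits_rejected(self):
        m = InvasibilityModel(_frame(np.linspace(0, 100, 12), np.zeros(12)))
        a = InvasibilityResults(m, [-0.01], [0.1], sse=100.0, df=10, nobs=11)
        c = InvasibilityResults(m, [-0.01, 0.0], [0.1, 0.1], sse=80.0, df=8, nobs=10)
        with pytest.raises(ValueError):
            nested_f_test(a, c)

    def test_nesting_monotonicity_on_noisy_data(self, default_trial):
        """Adding a parameter never increases SSE, so F >= 0 and p in [0, 1]."""
        ds, _ = default_trial
        for site in (3, 10, 11):
            null = InvasibilityModel(ds, site=site).fit()
            for variant in ("plus_SR", "plus_FR"):
                ext = InvasibilityModel(ds, site=site, variant=variant).fit()
                assert ext.sse <= null.sse + 1e-6
                f = ext.compare_f_test(null)
                assert f.f_value >= 0.0
                assert 0.0 <= f.p_value <= 1.0

    def test_seeded_richness_flag(self, default_trial):
        ds, _ = default_trial
        res = InvasibilityModel(ds, site=10, variant="plus_SR", richness="seeded").fit()
        assert res.params.size == 2


class TestParameterRecovery:
    def test_known_control_mean_recovery(self, single_weed_site_config):
        """With the true normalizer, beta1 is recovered within a few SEM."""
        cfg = single_weed_site_config(2024)
        ds, truth = cm.generate(cfg)
        res = InvasibilityModel(
            ds, site=11, control_mean=cfg.weed_control_mean
        ).fit()
        assert abs(res.beta1 - truth.beta1_true[11]) < 4 * res.bse[0]
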