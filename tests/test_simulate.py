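"""Synthetic trial generator: expectations, reproducibility, scenarios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import covermix as cm
from covermix.io import total_cover_biomass, total_weed_biomass
from covermix.simulate import (
    DEFAULT_SPECIES_MEANS,
    SiteSpec,
    SyntheticConfig,
    expected_mixture_biomass,
    legume_drawdown_scenario,
)


def _two_species_config(mu_a=300.0, mu_b=100.0, gamma=1.0):
    means = dict(DEFAULT_SPECIES_MEANS)
    means["BAR"], means["OAT"] = mu_a, mu_b
    return SyntheticConfig(species_means=means, gamma=gamma)


class TestExpectedMixtureBiomass:
    def test_pure_stand_reduces_to_species_mean(self, catalog):
        cfg = _two_species_config()
        site = SiteSpec(1, productivity_multiplier=1.0)
        assert expected_mixture_biomass(cfg, catalog.treatment(2), site) == pytest.approx(300.0)

    def test_site_multiplier_scales(self, catalog):
        cfg = _two_species_config()
        site = SiteSpec(1, productivity_multiplier=0.5)
        assert expected_mixture_biomass(cfg, catalog.treatment(2), site) == pytest.approx(150.0)

    def test_gamma_zero_gives_plain_mean(self, catalog):
        # two-species mixture stand-in: treatment with BAR and OAT only
        from covermix.catalog import TreatmentDefinition

        trt = TreatmentDefinition(99, frozenset({"BAR", "OAT"}), "cool")
        cfg = _two_species_config(gamma=0.0)
        site = SiteSpec(1)
        assert expected_mixture_biomass(cfg, trt, site) == pytest.approx(200.0)

    def test_large_gamma_approaches_dominant(self, catalog):
        from covermix.catalog import TreatmentDefinition

        trt = TreatmentDefinition(99, frozenset({"BAR", "OAT"}), "cool")
        cfg = _two_species_config(gamma=50.0)
        assert expected_mixture_biomass(cfg, trt, SiteSpec(1)) == pytest.approx(300.0, rel=1e-6)

    def test_control_errors(self, catalog):
        with pytest.raises(ValueError, match="control"):
            expected_mixture_biomass(SyntheticConfig(), catalog.treatment(1), SiteSpec(1))

    @given(
        mu=st.lists(st.floats(1.0, 1000.0), min_size=2, max_size=9),
        gamma=st.floats(0.0, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_never_exceeds_best_pure_stand(self, mu, gamma):
        """Dominance-weighted mean is bounded by the max constituent."""
        mu_arr = np.array(mu)
        w = mu_arr**gamma
        mix = np.sum(mu_arr * w) / np.sum(w)
        assert mix <= mu_arr.max() + 1e-9
        assert mix >= mu_arr.min() - 1e-9


class TestGenerate:
    def test_noise_free_plots_equal_expectation(self, noise_free_trial):
        ds, truth = noise_free_trial
        for o in ds:
            expect = truth.expected_biomass[(o.site_id, o.treatment_id)]
            assert total_cover_biomass(o) == pytest.approx(expect, abs=1e-9)

    def test_noise_free_weed_curve_exact(self, noise_free_trial):
        ds, truth = noise_free_trial
        cfg = truth.config
        for o in ds:
            if not o.weed_biomass_by_taxon:
                continue
            x = total_cover_biomass(o)
            b1 = truth.beta1_true[o.site_id]
            assert total_weed_biomass(o) == pytest.approx(
                cfg.weed_control_mean * np.exp(b1 * x), rel=1e-12
            )

    def test_same_seed_identical(self):
        ds1, _ = cm.generate(cm.default_config(5))
        ds2, _ = cm.generate(cm.default_config(5))
        assert len(ds1) == len(ds2)
        for a, b in zip(ds1, ds2):
            assert a.key == b.key
            assert a.cover_biomass_by_species == b.cover_biomass_by_species
            assert a.weed_biomass_by_taxon == b.weed_biomass_by_taxon

    def test_site_substreams_independent(self):
        """Dropping a site leaves the other sites' data unchanged."""
        cfg_full = cm.default_config(5)
        cfg_sub = cm.default_config(5, sites=tuple(s for s in cfg_full.sites if s.site_id != 3))
        full, _ = cm.generate(cfg_full)
        sub, _ = cm.generate(cfg_sub)
        full_map = {o.key: o for o in full if o.site_id != 3}
        sub_map = {o.key: o for o in sub}
        assert full_map.keys() == sub_map.keys()
        for k in full_map:
            assert full_map[k].cover_biomass_by_species == sub_map[k].cover_biomass_by_species

    def test_design_shape(self, default_trial):
        ds, _ = default_trial
        # 5 cool sites: 4 blocks x 20 trts (site 3 doubled by quadrats);
        # 2014 sites: 40 trts x 4 and x 3 blocks
        assert len(ds) == 160 + 4 * 80 + 160 + 120

    def test_control_plot_mean_weeds_lln(self):
        """Mean weed biomass over many control plots approaches its expectation."""
        site = SiteSpec(3, n_blocks=60, year=2013, n_quadrats_per_plot=1, weed_sampled=True)
        cfg = cm.default_config(11, sites=(site,))
        ds, _ = cm.generate(cfg)
        w = np.array([total_weed_biomass(o) for o in ds if o.treatment_id == 1])
        se = cfg.weed_control_mean * cfg.weed_cv / np.sqrt(w.size)
        assert abs(w.mean() - cfg.weed_control_mean) < 3 * se

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(beta1_true=0.01)
        with pytest.raises(ValueError):
            SyntheticConfig(species_cv=-0.1)
        bad_means = dict(DEFAULT_SPECIES_MEANS, BAR=-5.0)
        with pytest.raises(ValueError):
            SyntheticConfig(species_means=bad_means)


class TestDropout:
    def test_dropout_preserves_expected_total(self):
        """Dropout changes realized richness, not expected plot biomass."""
        site = SiteSpec(10, n_blocks=120, year=2014, n_quadrats_per_plot=1)
        cfg = cm.default_config(3, sites=(site,), species_cv=0.0, block_sd=0.0, weed_cv=0.0)
        ds, truth = cm.generate(cfg)
        x17 = np.array([total_cover_biomass(o) for o in ds if o.treatment_id == 17])
        expect = truth.expected_biomass[(10, 17)]
        # noise off: variation comes only from which species drop; the mean
        # stays at the closed-form expectation (compensation property)
        assert abs(x17.mean() - expect) / expect < 0.02

    def test_realized_deficit_grows_with_seeded_richness(self, default_trial, catalog):
        ds, _ = default_trial
        table = cm.richness_table(ds, catalog)
        deficit = (
            (table["seeded_sr"] - table["realized_sr"])
            .groupby(table["seeded_sr"])
            .mean()
        )
        assert deficit.loc[1] == 0
        assert deficit.loc[9] > deficit.loc[3]
        assert deficit.loc[18] > deficit.loc[9]


class TestLegumeDrawdownScenario:
    def test_contrast_structure(self, catalog):
        cfg = legume_drawdown_scenario()
        truth_es = cm.generate(
            cm.default_config(
                1, species_means=cfg.species_means, species_cv=0.0, block_sd=0.0,
                weed_cv=0.0, dropout_base=0.0,
            )
        )[1].expected_effect_sizes
        assert truth_es["fr"] > 0
        assert truth_es["sr_within_mean"] == pytest.approx(0.0, abs=1e-9)
        assert truth_es["sr_functional"] == pytest.approx(0.0, abs=1e-9)

    def test_legumes_at_twenty_percent(self, catalog):
        cfg = legume_drawdown_scenario()
        cl = [cfg.species_means[c] for c in ("PEA", "RED", "YEL")]
        grass_brassica = np.mean(
            [cfg.species_means[c] for c in ("BAR", "OAT", "WHT", "RAD", "RAPE", "TURN")]
        )
        assert all(v == pytest.approx(0.2 * grass_brassica) for v in cl)

    def test_no_mixture_exceeds_best_pure_stand(self, catalog):
        cfg = legume_drawdown_scenario()
        site = SiteSpec(1)
        for t in catalog.treatments:
            if len(t.species_codes) < 2:
                continue
            mix = expected_mixture_biomass(cfg, t, site)
            best = max(cfg.species_means[c] for c in t.species_codes)
            assert mix <= best + 1e-9
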