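"""Nutrient retention, lognormal parameter uncertainty, and mass balance."""

import math

import numpy as np
import pytest
from scipy import stats

from paddywf.hydrology import ManagementStyle
from paddywf.nutrients import (ConcState, FertilizationEvent, NutrientParams,
                               apply_fertilization, fit_lognormal_from_range,
                               params_to_frame, retention_flux,
                               sample_retention_params)
from paddywf.simulate import run_hydrology_season, run_nutrient_season

from conftest import make_config


class TestLognormalFit:
    def test_quantile_inversion_against_closed_form(self):
        mu, sigma = fit_lognormal_from_range(4.2, 44.0, coverage=0.90)
        z = stats.norm.ppf(0.95)
        assert mu == pytest.approx((math.log(4.2) + math.log(44.0)) / 2, abs=1e-9)
        assert sigma == pytest.approx((math.log(44.0) - math.log(4.2)) / (2 * z), abs=1e-9)
        assert mu == pytest.approx(2.609, abs=2e-3)
        assert sigma == pytest.approx(0.714, abs=2e-3)

    def test_degenerate_range_collapses_to_midpoint(self):
        mu, sigma = fit_lognormal_from_range(10.0, 10.0 + 1e-12)
        assert sigma == pytest.approx(0.0, abs=1e-9)
        assert math.exp(mu) == pytest.approx(10.0)

    def test_bounds_are_recovered_as_sample_quantiles(self):
        mu, sigma = fit_lognormal_from_range(4.2, 44.0, coverage=0.90)
        rng = np.random.default_rng(5)
        draws = np.exp(rng.normal(mu, sigma, 100_000))
        assert np.percentile(draws, 5) == pytest.approx(4.2, rel=0.01)
        assert np.percentile(draws, 95) == pytest.approx(44.0, rel=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal_from_range(-1.0, 5.0)
        with pytest.raises(ValueError):
            fit_lognormal_from_range(1.0, 5.0, coverage=1.5)


class TestParameterSampling:
    def test_draws_are_positive_and_reproducible(self):
        a = sample_retention_params(100, seed=3)
        b = sample_retention_params(100, seed=3)
        assert len(a) == 100
        assert a == b
        frame = params_to_frame(a)
        assert (frame > 0).all().all()

    def test_vf_p_coverage_near_nominal(self):
        draws = params_to_frame(sample_retention_params(100_000, seed=1))
        inside = draws["vf_p_cm_d"].between(1.5, 9.0).mean()
        assert inside == pytest.approx(0.90, abs=0.01)


class TestRetentionFlux:
    def test_zero_at_equilibrium(self):
        assert retention_flux(1.0, 1.0, 10.0, 1000.0, 500.0) == 0.0

    def test_unit_conversion_arithmetic(self):
        # vf 10 cm/d = 0.1 m/d; (3-1) mg/L = 2 g/m3; over 1000 m2 -> 200 g
        # (uncapped: the compartment holds ample mass)
        flux = retention_flux(3.0, 1.0, 10.0, 1000.0, volume_m3=10_000.0)
        assert flux == pytest.approx(200.0)

    def test_no_release_below_equilibrium(self):
        assert retention_flux(0.5, 1.0, 10.0, 1000.0, 500.0) == 0.0

    def test_cap_prevents_overshoot_below_equilibrium(self):
        # shallow volume: removable mass limited to (C - EC0) * V
        flux = retention_flux(3.0, 1.0, 50.0, 1000.0, volume_m3=100.0)
        assert flux == pytest.approx(2.0 * 100.0)


class TestFertilization:
    def test_reset_sets_field_concentrations_only(self):
        conc = ConcState(field_n_g=100.0, field_p_g=10.0, ditch_n_g=50.0)
        event = FertilizationEvent(0, 25.0, 1.5)
        new, dn, dp = apply_fertilization(conc, event, field_volume_m3=1000.0)
        assert new.field_n_g == pytest.approx(25_000.0)
        assert new.field_p_g == pytest.approx(1_500.0)
        assert new.ditch_n_g == 50.0
        assert dn == pytest.approx(24_900.0)

    def test_zero_event_clears_field(self):
        conc = ConcState(field_n_g=500.0)
        new, _, _ = apply_fertilization(conc, FertilizationEvent(0, 0.0, 0.0), 1000.0)
        assert new.field_n_g == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            FertilizationEvent(0, -1.0, 0.0)


def _mass_residual(nutr, nutrient):
    inputs = getattr(nutr, f"fert_input_{nutrient}_kg_ha")
    exports = (getattr(nutr, f"runoff_{nutrient}_kg_ha")
               + getattr(nutr, f"leach_{nutrient}_kg_ha")
               + getattr(nutr, f"retention_{nutrient}_kg_ha")
               + getattr(nutr, f"field_decay_{nutrient}_kg_ha"))
    delta = getattr(nutr, f"storage_delta_{nutrient}_kg_ha")
    return abs(inputs - exports - delta) / max(abs(inputs), 1e-9)


class TestSeasonMassBalance:
    @pytest.mark.parametrize("style", list(ManagementStyle))
    def test_fertilizer_mass_fully_accounted(self, cj_season, style):
        config = make_config(style)
        hydro = run_hydrology_season(*cj_season, config)
        params = sample_retention_params(1, seed=11)[0]
        nutr = run_nutrient_season(hydro, params, config)
        assert _mass_residual(nutr, "n") < 1e-6
        assert _mass_residual(nutr, "p") < 1e-6

    def test_pure_advection_when_retention_disabled(self, cj_season):
        """With vf ~ 0 and no decay, exports + storage match inputs and the
        ditch acts as a pass-through (no removal recorded)."""
        config = make_config(ManagementStyle.TC)
        config = type(config)(geometry=config.geometry, style=config.style,
                              scheme=config.scheme, crop=config.crop,
                              fert_events=config.fert_events,
                              field_decay_per_day=0.0)
        hydro = run_hydrology_season(*cj_season, config)
        params = NutrientParams(1e-9, 1e-9, 0.0, 0.0)
        nutr = run_nutrient_season(hydro, params, config)
        assert nutr.retention_n_kg_ha == pytest.approx(0.0, abs=1e-6)
        assert nutr.field_decay_n_kg_ha == 0.0
        assert _mass_residual(nutr, "n") < 1e-6
        assert nutr.runoff_n_kg_ha > 0.0

    def test_retention_monotone_in_uptake_velocity(self, cj_season, qd_config):
        hydro = run_hydrology_season(*cj_season, qd_config)
        removals = []
        for vf in (2.0, 10.0, 40.0):
            params = NutrientParams(vf, vf / 3, 0.1, 0.01)
            removals.append(run_nutrient_season(hydro, params, qd_config).retention_n_kg_ha)
        assert removals[0] < removals[1] <= removals[2]

    def test_qd_exports_no_more_than_tc_under_identical_forcing(self, cj_season):
        params = sample_retention_params(1, seed=21)[0]
        loads = {}
        for style in (ManagementStyle.TC, ManagementStyle.QD):
            config = make_config(style)
            hydro = run_hydrology_season(*cj_season, config)
            nutr = run_nutrient_season(hydro, params, config)
            loads[style] = nutr.runoff_n_kg_ha + nutr.leach_n_kg_ha
        assert loads[ManagementStyle.QD] <= loads[ManagementStyle.TC]
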