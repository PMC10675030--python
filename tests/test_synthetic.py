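"""Synthetic trial generator: determinism, invariants, observation
consistency with the truth, yield response and irrigation scheduling."""

import numpy as np
import pandas as pd
import pytest

from aeroeta.canopy import predict_lai
from aeroeta.synthetic import (
    FULL_IRRIGATION,
    RAINFED,
    TrialConfig,
    generate_flight_observations,
    generate_trial,
    generate_varieties,
    generate_weather,
    generate_yield,
    irrigation_schedule,
)
from tests.test_canopy import _table_model


class TestConfigValidation:
    def test_flight_ordering_and_early_flights_rejected(self):
        with pytest.raises(ValueError):
            TrialConfig(flight_das=(118, 110))
        with pytest.raises(ValueError):
            TrialConfig(flight_das=(95, 120))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            TrialConfig(vari_sd=-0.1)

    def test_single_variety_rejected(self):
        with pytest.raises(ValueError):
            TrialConfig(n_varieties=1)


class TestWeather:
    def test_deterministic_given_seed(self):
        cfg = TrialConfig(seed=42)
        a = generate_weather(cfg)
        b = generate_weather(cfg)
        assert all(
            (x.t_min, x.t_max, x.rainfall, x.et0) == (y.t_min, y.t_max,
                                                      y.rainfall, y.et0)
            for x, y in zip(a, b)
        )

    def test_zero_noise_is_smooth_and_ordered(self):
        days = generate_weather(TrialConfig(temp_noise_sd=0.0, seed=1))
        t_mean = np.array([d.t_mean for d in days])
        assert np.abs(np.diff(t_mean)).max() < 0.25  # pure seasonal sinusoid
        assert all(d.t_min <= d.t_max for d in days)

    def test_invariants_hold(self):
        for day in generate_weather(TrialConfig(seed=7)):
            assert 0.0 <= day.rh_mean <= 100.0
            assert day.rainfall >= 0.0
            assert day.wind_2m >= 0.0
            assert np.isfinite(day.solar_rad) and day.et0 >= 0.0

    def test_season_total_rainfall_on_target(self):
        cfg = TrialConfig(season_length=180, rainfall_total_mm=140.0, seed=3)
        total = sum(d.rainfall for d in generate_weather(cfg))
        assert total == pytest.approx(
            140.0, rel=cfg.rainfall_tolerance
        )

    def test_nonpositive_season_rejected(self):
        with pytest.raises(ValueError):
            TrialConfig(season_length=0)


@pytest.fixture(scope="module")
def zero_noise():
    cfg = TrialConfig(n_varieties=3, n_blocks=2, seed=9,
                      tc_unstressed=21.0).zero_noise()
    weather = generate_weather(cfg)
    varieties = generate_varieties(cfg)
    snaps = generate_flight_observations(varieties, weather, cfg)
    return cfg, varieties, snaps


class TestFlightObservations:
    def test_one_record_per_plot_and_flight(self, zero_noise):
        cfg, varieties, snaps = zero_noise
        n_flights = len(cfg.flight_das) + len(cfg.rgb_flight_das)
        assert len(snaps) == 3 * 2 * 2 * n_flights
        assert snaps.duplicated(["plot_id", "das"]).sum() == 0

    def test_lai_map_inversion_is_exact(self, zero_noise):
        cfg, varieties, snaps = zero_noise
        truth = {v.name: v for v in varieties}
        model = _table_model()  # generator uses the same default coefficients
        pred = predict_lai(model, snaps["PH"], snaps["VARI"], snaps["fc"])
        want = np.array(
            [truth[r.variety].lai(r.das) for r in snaps.itertuples()]
        )
        np.testing.assert_allclose(pred, want, atol=1e-9)

    def test_unstressed_canopy_at_configured_temperature(self, zero_noise):
        cfg, varieties, snaps = zero_noise
        irr = snaps[snaps.has_thermal & (snaps.treatment == FULL_IRRIGATION)]
        np.testing.assert_allclose(irr["t_c"], 21.0, atol=1e-12)

    def test_canopy_warming_tracks_stress_gap(self, zero_noise):
        cfg, varieties, snaps = zero_noise
        das = max(cfg.flight_das)
        for v in varieties:
            gap = 1.0 - v.ks(das, RAINFED)
            sel = snaps[(snaps.variety == v.name) & (snaps.das == das)]
            t_irr = sel[sel.treatment == FULL_IRRIGATION]["t_c"].mean()
            t_rf = sel[sel.treatment == RAINFED]["t_c"].mean()
            assert t_rf - t_irr == pytest.approx(cfg.tc_stress_gain * gap,
                                                 abs=1e-9)

    def test_flight_before_sowing_rejected(self):
        cfg = TrialConfig(n_varieties=2, n_blocks=1, rgb_flight_das=(-3,))
        weather = generate_weather(cfg)
        with pytest.raises(ValueError):
            generate_flight_observations(generate_varieties(cfg), weather, cfg)

    def test_determinism_of_full_trial(self):
        cfg = TrialConfig(n_varieties=2, n_blocks=1, seed=17)
        a = generate_trial(cfg)
        b = generate_trial(cfg)
        pd.testing.assert_frame_equal(a.snapshots, b.snapshots)
        pd.testing.assert_frame_equal(a.agronomy, b.agronomy)


class TestYieldResponse:
    def _eta_table(self, values):
        return pd.DataFrame(
            [
                {"variety": "Variety 1", "treatment": RAINFED, "block": 1,
                 "eta_gf": v}
                for v in values
            ]
        )

    @pytest.fixture()
    def config(self):
        return TrialConfig(n_varieties=2, n_blocks=1, variety_effect_sd=0.0,
                           seed=0).zero_noise()

    @pytest.fixture()
    def varieties(self, config):
        return generate_varieties(config)

    def test_offset_point_yields_nothing(self, config, varieties):
        table = generate_yield(
            varieties, self._eta_table([config.yield_offset_mm]), config
        )
        assert table["GY"].iloc[0] == 0.0

    def test_asymptote_reaches_ymax_times_effect(self, config, varieties):
        table = generate_yield(varieties, self._eta_table([1e6]), config)
        effect = varieties[0].variety_effect
        assert table["GY"].iloc[0] == pytest.approx(config.ymax * effect)

    def test_monotone_in_grain_filling_eta(self, config, varieties):
        table = generate_yield(
            varieties,
            self._eta_table([c + config.yield_offset_mm
                             for c in (10.0, 40.0, 80.0, 140.0)]),
            config,
        )
        gy = table["GY"].to_numpy()
        assert (np.diff(gy) > 0).all()
        assert (np.diff(table["TKW"].to_numpy()) > 0).all()

    def test_negative_ymax_rejected(self):
        with pytest.raises(ValueError):
            TrialConfig(ymax=-1.0)

    def test_negative_eta_rejected(self, config, varieties):
        with pytest.raises(ValueError):
            generate_yield(varieties, self._eta_table([-5.0]), config)


class TestIrrigationSchedule:
    def test_weekly_dose_arithmetic(self):
        doses = irrigation_schedule(
            np.full(7, 5.0), np.ones(7), np.zeros(7)
        )
        assert doses == pytest.approx([35.0])

    def test_rain_fully_covers_demand(self):
        doses = irrigation_schedule(
            np.full(14, 3.0), np.ones(14), np.full(14, 4.0)
        )
        assert (doses == 0.0).all()

    def test_rainfed_gets_nothing(self):
        doses = irrigation_schedule(
            np.full(14, 5.0), np.ones(14), np.zeros(14), treatment=RAINFED
        )
        assert (doses == 0.0).all() and len(doses) == 2

    def test_mismatched_series_rejected(self):
        with pytest.raises(ValueError):
            irrigation_schedule(np.ones(7), np.ones(6), np.zeros(7))


class TestTruthInvariants:
    def test_phenology_and_stress_invariants(self, noisy_trial):
        for v in noisy_trial.varieties:
            assert 0 < v.heading_das < v.maturity_das
            assert v.maturity_das <= noisy_trial.config.season_length
            das = np.arange(0, 101)
            assert (np.asarray(v.ks(das, RAINFED)) == 1.0).all()
            ks_end = float(v.ks(v.maturity_das, RAINFED))
            assert 0.0 < ks_end < 1.0
            assert float(v.ks(v.maturity_das, FULL_IRRIGATION)) == 1.0
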