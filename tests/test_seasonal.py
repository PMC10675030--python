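"""Ks interpolation, daily ETa integration, stage splits and water
productivity, including the exact round-trip identity of the step scheme."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aeroeta.seasonal import (
    KsPoint,
    Phenology,
    crop_stress_coefficient,
    daily_eta_series,
    interpolate_ks,
    stage_integrals,
    water_productivity,
)


class TestStressCoefficient:
    def test_ratio_values(self):
        assert crop_stress_coefficient(5.0, 5.0) == 1.0
        assert crop_stress_coefficient(2.5, 5.0) == 0.5

    def test_nonpositive_etp_rejected(self):
        with pytest.raises(ValueError):
            crop_stress_coefficient(2.0, 0.0)

    def test_not_capped_by_default_but_cappable(self):
        assert crop_stress_coefficient(6.0, 5.0) == pytest.approx(1.2)
        assert crop_stress_coefficient(6.0, 5.0, cap=1.0) == 1.0


class TestInterpolateKs:
    def test_no_flights_returns_unstressed_season(self):
        with pytest.warns(UserWarning):
            ks = interpolate_ks([], 170)
        assert (ks == 1.0).all() and len(ks) == 171

    def test_single_flight_holds_from_das_101(self):
        ks = interpolate_ks([KsPoint(das=120, ks=0.6)], 170)
        assert (ks[:101] == 1.0).all()
        assert (ks[101:] == 0.6).all()

    def test_midpoint_boundaries(self):
        ks = interpolate_ks(
            [KsPoint(das=118, ks=0.8), KsPoint(das=138, ks=0.6)], 160
        )
        assert (ks[:101] == 1.0).all()
        assert (ks[101:129] == 0.8).all()   # DAS 101..128
        assert (ks[129:161] == 0.6).all()   # DAS 129..160

    def test_early_flights_rejected(self):
        with pytest.raises(ValueError):
            interpolate_ks([KsPoint(das=95, ks=0.9)], 170)

    def test_linear_scheme_interpolates_between_flights(self):
        ks = interpolate_ks(
            [KsPoint(das=120, ks=0.8), KsPoint(das=140, ks=0.4)],
            160, scheme="linear",
        )
        assert ks[130] == pytest.approx(0.6)
        assert ks[150] == pytest.approx(0.4)
        assert (ks[:101] == 1.0).all()


class TestDailyEta:
    def test_elementwise_product_and_cumulative(self):
        eta, cum = daily_eta_series(np.full(10, 0.5), np.full(10, 4.0))
        assert (eta == 2.0).all()
        assert cum[-1] == pytest.approx(20.0)

    def test_unstressed_equals_potential(self):
        etp = np.linspace(1, 5, 30)
        eta, _ = daily_eta_series(np.ones(30), etp)
        np.testing.assert_array_equal(eta, etp)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            daily_eta_series(np.ones(5), np.ones(6))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 12), min_size=1, max_size=200))
    def test_cumulative_never_decreases(self, etp):
        _, cum = daily_eta_series(np.full(len(etp), 0.7), np.array(etp))
        assert (np.diff(cum) >= 0).all()


class TestStageIntegrals:
    def test_heading_day_belongs_to_vegetative_stage(self):
        phen = Phenology("v", heading_das=1, maturity_das=3)
        stages = stage_integrals(np.array([1.0, 2.0, 4.0, 8.0]), phen)
        assert stages.eta_veg == pytest.approx(3.0)
        assert stages.eta_gf == pytest.approx(12.0)

    def test_constant_rate_arithmetic(self):
        phen = Phenology("v", heading_das=100, maturity_das=160)
        stages = stage_integrals(np.full(161, 2.0), phen)
        assert stages.eta_veg == pytest.approx(202.0)
        assert stages.eta_gf == pytest.approx(120.0)
        assert stages.eta_total == pytest.approx(322.0)

    def test_partition_identity_random_series(self):
        rng = np.random.default_rng(0)
        eta = rng.uniform(0, 8, 171)
        phen = Phenology("v", heading_das=130, maturity_das=170)
        stages = stage_integrals(eta, phen)
        assert stages.eta_veg + stages.eta_gf == pytest.approx(
            stages.eta_total, abs=1e-9
        )
        assert stages.eta_total == pytest.approx(eta.sum(), abs=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            stage_integrals(np.ones(100), Phenology("v", 50, 160))


class TestWaterProductivity:
    def test_unit_conversion(self):
        assert water_productivity(1000.0, 100.0) == pytest.approx(1.0)
        assert water_productivity(0.0, 100.0) == 0.0

    def test_published_variety_row(self):
        # 8122.2 kg/ha over 255.4 mm -> 3.2 kg/m3 at one decimal
        assert round(water_productivity(8122.2, 255.4), 1) == 3.2

    def test_nonpositive_eta_rejected(self):
        with pytest.raises(ValueError):
            water_productivity(5000.0, 0.0)


class TestRoundTrip:
    def test_step_aligned_truth_reproduced_exactly(self):
        """Piecewise-constant truth with breakpoints on the midpoint
        boundaries survives Ks -> interpolation -> integration to 1e-9 mm."""
        maturity = 162
        flights = [118, 138, 155]
        levels = [0.9, 0.7, 0.5]
        rng = np.random.default_rng(2)
        etp = rng.uniform(2.0, 6.5, maturity + 1)
        ks_true = np.ones(maturity + 1)
        bounds = [101, 129, 147, maturity + 1]  # midpoint boundaries
        for lo, hi, level in zip(bounds[:-1], bounds[1:], levels):
            ks_true[lo:hi] = level
        eta_true = ks_true * etp

        points = [
            KsPoint(das=f, ks=crop_stress_coefficient(eta_true[f], etp[f]))
            for f in flights
        ]
        ks_daily = interpolate_ks(points, maturity)
        eta, cum = daily_eta_series(ks_daily, etp)
        assert abs(cum[-1] - eta_true.sum()) < 1e-9
        np.testing.assert_allclose(eta, eta_true, atol=1e-12)

    def test_piecewise_linear_truth_within_five_percent(self):
        """Linear Ks declines sampled by >= 3 reproductive-window flights
        integrate to within 5% of the exact integral."""
        maturity = 162
        flights = [118, 131, 145, 155]
        rng = np.random.default_rng(5)
        worst = 0.0
        for _ in range(100):
            etp = rng.uniform(2.5, 6.0, maturity + 1)
            onset = rng.integers(110, 135)
            ks_end = rng.uniform(0.3, 0.9)
            das = np.arange(maturity + 1)
            ks_true = np.ones(maturity + 1)
            m = das > onset
            ks_true[m] = 1 - (1 - ks_end) * (das[m] - onset) / (maturity - onset)
            eta_true = ks_true * etp
            points = [
                KsPoint(das=f, ks=crop_stress_coefficient(eta_true[f], etp[f]))
                for f in flights
            ]
            _, cum = daily_eta_series(interpolate_ks(points, maturity), etp)
            worst = max(worst, abs(cum[-1] - eta_true.sum()) / eta_true.sum())
        assert worst < 0.05
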