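"""Soil water budget, texture pedotransfer and the moisture rate modifier."""

import numpy as np
import pytest

from rothc_grass import (
    WaterState,
    pedotransfer_water,
    rate_modifier_moisture,
    saxton_rawls_theta,
    update_smd,
)


class TestPedotransfer:
    def test_reference_max_deficit_at_normalizing_depth(self):
        # clay 23 %, depth 23 cm: 20.0 + 1.3*23 - 0.01*23^2 = 44.61 mm
        b = pedotransfer_water(clay=23.0, sand=40.0, silt=37.0, depth_cm=23.0)
        assert b.max_smd_vegetated == pytest.approx(44.61, abs=1e-9)
        assert b.max_smd_bare == pytest.approx(44.61 / 1.8, abs=1e-9)

    def test_saturation_exceeds_field_capacity(self):
        for clay, sand in [(10, 70), (25, 40), (45, 20)]:
            fc, sat = saxton_rawls_theta(clay, sand)
            assert sat > fc > 0.0

    def test_saturation_bound_is_negative(self):
        b = pedotransfer_water(clay=30.0, sand=30.0, silt=40.0, depth_cm=20.0)
        assert b.smd_saturation < 0.0
        assert b.smd_saturation == pytest.approx(
            -(b.theta_sat - b.theta_fc) * 20.0 * 10.0
        )

    def test_theta_override_bypasses_texture(self):
        b = pedotransfer_water(
            clay=30.0, sand=30.0, silt=40.0, depth_cm=20.0, theta_override=(0.30, 0.45)
        )
        assert b.smd_saturation == pytest.approx(-30.0)

    def test_rejects_bad_texture(self):
        with pytest.raises(ValueError):
            pedotransfer_water(clay=50.0, sand=40.0, silt=30.0, depth_cm=20.0)


class TestUpdateSmd:
    def test_balanced_budget_leaves_deficit_unchanged(self, loam_bounds):
        s = WaterState(smd=12.0)
        out = update_smd(s, rain=30.0, evap=40.0, vegetated=True,
                         bounds=loam_bounds, allow_saturation=True)
        assert out.smd == pytest.approx(12.0)

    def test_clamped_at_saturation(self, loam_bounds):
        s = WaterState(smd=loam_bounds.smd_saturation)
        out = update_smd(s, rain=300.0, evap=0.0, vegetated=True,
                         bounds=loam_bounds, allow_saturation=True)
        assert out.smd == loam_bounds.smd_saturation

    def test_default_mode_floors_at_field_capacity(self, loam_bounds):
        s = WaterState(smd=0.0)
        out = update_smd(s, rain=200.0, evap=10.0, vegetated=True,
                         bounds=loam_bounds, allow_saturation=False)
        assert out.smd == 0.0

    def test_bare_soil_uses_smaller_cap(self, loam_bounds):
        s = WaterState(smd=loam_bounds.max_smd_vegetated)
        out = update_smd(s, rain=0.0, evap=100.0, vegetated=False,
                         bounds=loam_bounds, allow_saturation=False)
        assert out.smd == loam_bounds.max_smd_bare

    def test_pet_factor_switch(self, loam_bounds):
        s = WaterState(smd=0.0)
        out = update_smd(s, rain=0.0, evap=40.0, vegetated=True,
                         bounds=loam_bounds, allow_saturation=False, evap_factor=1.0)
        assert out.smd == pytest.approx(40.0)


class TestMoistureFactor:
    def test_saturation_gives_minimum_rate(self, loam_bounds):
        b = rate_modifier_moisture(loam_bounds.smd_saturation, loam_bounds, extended=True)
        assert b == pytest.approx(0.2, abs=1e-12)

    def test_field_capacity_gives_one(self, loam_bounds):
        assert rate_modifier_moisture(0.0, loam_bounds, extended=True) == 1.0

    def test_wet_side_midpoint(self, loam_bounds):
        mid = 0.5 * loam_bounds.smd_saturation
        assert rate_modifier_moisture(mid, loam_bounds, extended=True) == pytest.approx(0.6)

    def test_dry_plateau_and_dry_limit(self, loam_bounds):
        m = loam_bounds.max_smd_vegetated
        assert rate_modifier_moisture(0.4 * m, loam_bounds, extended=True) == 1.0
        assert rate_modifier_moisture(m, loam_bounds, extended=True) == pytest.approx(0.2)

    def test_continuous_and_bounded_over_whole_domain(self, loam_bounds):
        grid = np.linspace(loam_bounds.smd_saturation, loam_bounds.max_smd_vegetated, 2001)
        vals = np.array(
            [rate_modifier_moisture(s, loam_bounds, extended=True) for s in grid]
        )
        assert (vals >= 0.2 - 1e-12).all() and (vals <= 1.0 + 1e-12).all()
        # continuity: step between adjacent grid points bounded by local slope
        assert np.abs(np.diff(vals)).max() < 0.005

    def test_non_increasing_away_from_plateau(self, loam_bounds):
        wet = np.linspace(0.0, loam_bounds.smd_saturation, 100)  # toward saturation
        dry = np.linspace(0.0, loam_bounds.max_smd_vegetated, 100)  # toward dryness
        wet_vals = [rate_modifier_moisture(s, loam_bounds, extended=True) for s in wet]
        dry_vals = [rate_modifier_moisture(s, loam_bounds, extended=True) for s in dry]
        assert np.all(np.diff(wet_vals) <= 1e-12)
        assert np.all(np.diff(dry_vals) <= 1e-12)

    def test_extended_never_exceeds_default(self, loam_bounds):
        # on the attainable default-mode domain both agree; below field
        # capacity only the extended factor exists and it is < 1
        for smd in np.linspace(0.0, loam_bounds.max_smd_vegetated, 50):
            ext = rate_modifier_moisture(smd, loam_bounds, extended=True)
            default = rate_modifier_moisture(smd, loam_bounds, extended=False)
            assert ext <= default + 1e-12
        assert rate_modifier_moisture(-5.0, loam_bounds, extended=True) < 1.0

    def test_out_of_range_rejected(self, loam_bounds):
        with pytest.raises(ValueError):
            rate_modifier_moisture(
                loam_bounds.max_smd_vegetated + 5.0, loam_bounds, extended=True
            )
        with pytest.raises(ValueError):
            rate_modifier_moisture(
                loam_bounds.smd_saturation - 5.0, loam_bounds, extended=True
            )
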