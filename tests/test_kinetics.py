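"""Five-pool decomposition engine: rate modifiers, clay partition, stepping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rothc_grass import (
    CarbonState,
    DecayConstants,
    PoolAdditions,
    RateModifiers,
    partition_decomposed,
    rate_modifier_cover,
    rate_modifier_temperature,
    step_month,
)
from rothc_grass.kinetics import DEFAULT_DECAY_CONSTANTS


class TestTemperatureFactor:
    def test_zero_below_cutoff(self):
        assert rate_modifier_temperature(-20.0) == 0.0
        assert rate_modifier_temperature(-18.27) == 0.0

    def test_closed_form_value(self):
        # hand evaluation of 47.91 / (1 + exp(106.06 / (9.25 + 18.27)))
        assert rate_modifier_temperature(9.25) == pytest.approx(0.994, abs=5e-4)

    def test_strictly_increasing(self):
        assert (
            rate_modifier_temperature(15.0)
            > rate_modifier_temperature(5.0)
            > rate_modifier_temperature(0.0)
            > 0.0
        )

    def test_continuous_at_cutoff(self):
        assert rate_modifier_temperature(-18.26) < 1e-6

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            rate_modifier_temperature(float("nan"))


def test_cover_factor_values():
    assert rate_modifier_cover(True) == 0.6
    assert rate_modifier_cover(False) == 1.0


class TestClayPartition:
    def test_zero_in_zero_out(self):
        assert partition_decomposed(0.0, 30.0) == (0.0, 0.0, 0.0)

    def test_conservation_and_bio_hum_split(self):
        co2, bio, hum = partition_decomposed(3.7, 25.0)
        assert co2 + bio + hum == pytest.approx(3.7, rel=1e-15)
        assert bio / (bio + hum) == pytest.approx(0.46, rel=1e-12)

    def test_high_clay_co2_limit(self):
        # x -> 1.67 * 1.85 as clay grows, so CO2 share -> x/(1+x) ~ 0.755
        co2, bio, hum = partition_decomposed(1.0, 100.0)
        assert co2 == pytest.approx(0.755, abs=2e-3)

    def test_retained_share_increases_with_clay(self):
        retained = [sum(partition_decomposed(1.0, c)[1:]) for c in (0, 10, 25, 40, 60)]
        assert np.all(np.diff(retained) > 0)

    def test_rejects_negative_carbon(self):
        with pytest.raises(ValueError):
            partition_decomposed(-0.1, 20.0)


def _state(dpm=1.0, rpm=10.0, bio=2.0, hum=50.0, iom=5.0):
    return CarbonState(dpm=dpm, rpm=rpm, bio=bio, hum=hum, iom=iom)


class TestStepMonth:
    def test_frozen_soil_without_inputs_is_identity(self):
        s = _state()
        out = step_month(s, RateModifiers(a=0.0, b=1.0, c=1.0), PoolAdditions(), 25.0)
        assert out == s

    def test_inputs_only_credit_entry_pools_exactly(self):
        s = _state()
        adds = PoolAdditions(dpm=0.4, rpm=0.6, hum=0.25)
        out = step_month(s, RateModifiers(a=0.0, b=1.0, c=1.0), adds, 25.0)
        assert out.dpm == s.dpm + 0.4
        assert out.rpm == s.rpm + 0.6
        assert out.hum == s.hum + 0.25
        assert out.cumulative_co2 == 0.0

    def test_twelve_steps_match_annual_closed_form(self):
        # a single pool decaying for 12 months equals C * exp(-k * a*b*c)
        mods = RateModifiers(a=0.8, b=0.7, c=0.6)
        s = CarbonState(dpm=0.0, rpm=7.0, bio=0.0, hum=0.0, iom=0.0)
        for _ in range(12):
            s = step_month(s, mods, PoolAdditions(), clay=0.0)
        expected = 7.0 * math.exp(-0.3 * mods.product)
        assert s.rpm == pytest.approx(expected, rel=1e-12)

    def test_iom_constant_and_active_soc_declines_without_inputs(self):
        s = _state()
        mods = RateModifiers(a=1.0, b=0.8, c=0.6)
        prev_active = s.active_soc
        for _ in range(24):
            s = step_month(s, mods, PoolAdditions(), 25.0)
            assert s.iom == 5.0
            assert s.active_soc < prev_active
            prev_active = s.active_soc

    def test_analytic_decay_matches_fine_step_ode_oracle(self):
        """Monthly exponential decay vs brute-force Euler of the ODE (<= 0.5 %)."""
        mods = RateModifiers(a=1.0, b=1.0, c=1.0)
        k = DEFAULT_DECAY_CONSTANTS
        s = step_month(_state(), mods, PoolAdditions(), clay=25.0)
        n = 24 * 30  # sub-daily Euler steps over one month
        dt = mods.product / 12.0 / n
        oracle = {"dpm": 1.0, "rpm": 10.0, "bio": 2.0, "hum": 50.0}
        rates = {"dpm": k.k_dpm, "rpm": k.k_rpm, "bio": k.k_bio, "hum": k.k_hum}
        for _ in range(n):
            decomposed = {p: oracle[p] * rates[p] * dt for p in oracle}
            total = sum(decomposed.values())
            co2, bio_in, hum_in = partition_decomposed(total, 25.0)
            for p in oracle:
                oracle[p] -= decomposed[p]
            oracle["bio"] += bio_in
            oracle["hum"] += hum_in
        for pool in ("dpm", "rpm", "bio", "hum"):
            assert getattr(s, pool) == pytest.approx(oracle[pool], rel=5e-3)

    @given(
        dpm=st.floats(0, 20),
        rpm=st.floats(0, 50),
        bio=st.floats(0, 10),
        hum=st.floats(0, 150),
        a=st.floats(0, 4),
        b=st.floats(0.2, 1),
        clay=st.floats(0, 60),
        in_dpm=st.floats(0, 2),
        in_rpm=st.floats(0, 2),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_pools_stay_non_negative_and_mass_balances(
        self, dpm, rpm, bio, hum, a, b, clay, in_dpm, in_rpm
    ):
        s = CarbonState(dpm=dpm, rpm=rpm, bio=bio, hum=hum, iom=3.0)
        adds = PoolAdditions(dpm=in_dpm, rpm=in_rpm)
        out = step_month(s, RateModifiers(a=a, b=b, c=0.6), adds, clay)
        assert min(out.dpm, out.rpm, out.bio, out.hum) >= 0.0
        delta = out.total_soc - s.total_soc
        net = adds.total - out.cumulative_co2
        scale = max(s.total_soc, adds.total, 1.0)
        assert abs(delta - net) <= 1e-9 * scale


def test_decay_constants_ordering_enforced():
    with pytest.raises(ValueError):
        DecayConstants(k_dpm=0.1, k_rpm=0.3, k_bio=0.66, k_hum=0.02)
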