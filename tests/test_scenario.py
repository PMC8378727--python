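"""Scenario runner, version ladder, fixtures and file round-trips."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from rothc_grass import (
    VERSION_LADDER,
    generate_fixture,
    run_scenario,
)
from rothc_grass.io import (
    load_config,
    load_weather,
    read_results,
    save_config,
    write_results,
)


def _ladder_socs(config, weather):
    return {
        v: run_scenario(config.with_version(v), weather).final_soc
        for v in VERSION_LADDER
    }


class TestRunScenario:
    def test_deterministic_given_config_and_weather(self, wet_grazed):
        weather, config, _ = wet_grazed
        a = run_scenario(config, weather)
        b = run_scenario(config, weather)
        assert a.monthly.equals(b.monthly)
        assert a.final_soc == b.final_soc

    def test_mass_balance_audit_tight(self, wet_grazed):
        weather, config, _ = wet_grazed
        for v in VERSION_LADDER:
            res = run_scenario(config.with_version(v), weather)
            assert res.mass_balance_error <= 1e-9

    def test_result_shape_and_annual_summary(self, wet_grazed):
        weather, config, _ = wet_grazed
        res = run_scenario(config, weather)
        assert res.n_months == len(weather)
        assert len(res.annual) == len(weather) // 12
        dec = res.monthly[res.monthly["month"] == 12]["soc_total"].to_numpy()
        assert np.allclose(res.annual["soc_mg_ha"].to_numpy(), dec)

    def test_iom_constant_throughout(self, wet_grazed):
        weather, config, _ = wet_grazed
        res = run_scenario(config, weather)
        assert res.monthly["iom"].nunique() == 1

    def test_version_ladder_ordering_on_wet_site(self, wet_grazed):
        weather, config, _ = wet_grazed
        socs = _ladder_socs(config, weather)
        assert socs["RothC_0"] == min(socs.values())
        assert socs["RothC_3"] > socs["RothC_2"] > socs["RothC_1"] > socs["RothC_0"]
        assert socs["RothC_4"] <= socs["RothC_3"]

    def test_version_ladder_ordering_on_wet_cut_site(self, wet_cut):
        weather, config, _ = wet_cut
        socs = _ladder_socs(config, weather)
        assert socs["RothC_0"] == min(socs.values())
        # no grazing: poaching can never fire, the top two versions coincide
        assert socs["RothC_4"] == socs["RothC_3"]

    def test_poaching_inert_on_dry_site(self, dry_grazed):
        weather, config, _ = dry_grazed
        r3 = run_scenario(config.with_version("RothC_3"), weather)
        r4 = run_scenario(config.with_version("RothC_4"), weather)
        assert r4.monthly.equals(r3.monthly)
        assert not r4.monthly["poaching_flag"].any()

    def test_poaching_fires_and_reduces_soc_on_wet_grazed_site(self, wet_grazed):
        weather, config, _ = wet_grazed
        r3 = run_scenario(config.with_version("RothC_3"), weather)
        r4 = run_scenario(config.with_version("RothC_4"), weather)
        assert r4.monthly["poaching_flag"].any()
        assert r4.final_soc < r3.final_soc

    def test_missing_weather_month_rejected(self, wet_grazed):
        weather, config, _ = wet_grazed
        gappy = weather.drop(index=7).reset_index(drop=True)
        with pytest.raises(ValueError, match="gap"):
            run_scenario(config, gappy)

    def test_spinup_initialization_matches_measured_stock(self, wet_grazed):
        weather, config, _ = wet_grazed
        res = run_scenario(replace(config, init_method="spinup"), weather)
        assert res.initial_state.total_soc == pytest.approx(
            config.site.initial_soc, rel=1e-9
        )


class TestFixtures:
    def test_pure_function_of_seed(self):
        w1, c1, o1 = generate_fixture(42, "wet_grazed")
        w2, c2, o2 = generate_fixture(42, "wet_grazed")
        assert w1.equals(w2) and c1 == c2 and o1.equals(o2)
        w3, _, _ = generate_fixture(43, "wet_grazed")
        assert not w3.equals(w1)

    def test_wet_profile_climate_envelope(self, wet_grazed):
        weather, config, _ = wet_grazed
        annual_rain = weather.groupby("year")["precip_mm"].sum()
        assert (annual_rain > 1000.0).all()
        assert 7.0 <= weather["tmean_c"].mean() <= 10.6

    def test_wet_site_reaches_saturation_proximity_each_year(self, wet_grazed):
        weather, config, _ = wet_grazed
        res = run_scenario(config.with_version("RothC_3"), weather)
        wet_months = res.monthly[res.monthly["smd_mm"] <= -10.0]
        assert set(wet_months["year"].unique()) == set(weather["year"].unique())

    def test_dry_site_never_approaches_saturation(self, dry_grazed):
        weather, config, _ = dry_grazed
        res = run_scenario(config.with_version("RothC_3"), weather)
        grazing_months = [m + 1 for m, g in enumerate(config.management.grazing) if g]
        grazed = res.monthly[res.monthly["month"].isin(grazing_months)]
        assert (grazed["smd_mm"] > -10.0).all()

    def test_management_envelope(self, wet_grazed):
        _, config, _ = wet_grazed
        assert 183.0 <= config.management.n_input <= 229.0
        assert 64.7 <= config.site.initial_soc <= 137.0
        assert 20.0 <= config.site.clay <= 35.0
        assert 1.0 <= config.management.stocking_rate <= 2.0

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError):
            generate_fixture(1, "alpine")


class TestFileRoundTrips:
    def test_config_yaml_round_trip(self, tmp_path, wet_grazed):
        _, config, _ = wet_grazed
        path = tmp_path / "config.yaml"
        save_config(config, path)
        assert load_config(path) == config

    def test_config_version_override(self, tmp_path, wet_grazed):
        _, config, _ = wet_grazed
        path = tmp_path / "config.yaml"
        save_config(config, path)
        cfg0 = load_config(path, version="RothC_0")
        assert not cfg0.flags.excreta_quality

    def test_weather_csv_round_trip(self, tmp_path, wet_grazed):
        weather, _, _ = wet_grazed
        path = tmp_path / "weather.csv"
        weather.to_csv(path, index=False)
        assert load_weather(path).equals(weather)

    def test_results_csv_round_trip(self, tmp_path, wet_grazed):
        weather, config, _ = wet_grazed
        res = run_scenario(config, weather)
        path = write_results(res, tmp_path)
        assert read_results(path).equals(res.monthly)

    def test_weather_gap_diagnosed_on_load(self, tmp_path, wet_grazed):
        weather, _, _ = wet_grazed
        path = tmp_path / "weather.csv"
        weather.drop(index=4).to_csv(path, index=False)
        with pytest.raises(ValueError, match="2004-05"):
            load_weather(path)

    def test_poaching_without_grazing_accepted_with_warning(self, wet_cut, caplog):
        weather, config, _ = wet_cut
        cfg = config.with_version("RothC_4")
        import logging

        with caplog.at_level(logging.WARNING, logger="rothc_grass.simulate"):
            run_scenario(cfg, weather)
        assert any("inert" in rec.message for rec in caplog.records)
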