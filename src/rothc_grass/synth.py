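"""Seeded synthetic-site fixtures for temperate moist managed grassland.

The generator emulates the climate and management envelope of intensive
European grassland flux sites: annual precipitation above 1000 mm and mean
air temperature between 7 and 10.6 degC for the wet profiles, grazing from
May to October at 1-2 LSU ha-1 (or a four-cut mowing calendar), nitrogen
input of 183-229 kg N ha-1 yr-1, initial topsoil SOC of 64.7-137 Mg C ha-1
and clay of 20-35 %.  The ``dry_grazed`` profile uses the same management
under a rain-limited climate in which the soil never approaches saturation,
so poaching can never trigger.

Fixtures are pure functions of the seed: weather, configuration and the
synthetic observations (a reference-model run plus observation noise) are
all drawn from one ``numpy`` generator in a fixed order.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .config import ManagementCalendar, ModelConfig, SiteProfile, preset_flags
from .eom import DEFAULT_RUMINANT_QUALITY, EOMApplication, EOMQuality

__all__ = ["generate_fixture", "FIXTURE_PROFILES"]

FIXTURE_PROFILES = ("wet_grazed", "wet_cut", "dry_grazed")

# monthly climatology (Jan..Dec); wet profile totals ~1180 mm rain, ~670 mm
# open-pan evaporation; dry profile ~390 mm rain against ~860 mm evaporation
_WET_RAIN = np.array([110.0, 95, 90, 85, 90, 85, 80, 90, 100, 115, 120, 120])
_WET_EVAP = np.array([15.0, 25, 45, 70, 95, 105, 100, 85, 60, 35, 20, 12])
_DRY_RAIN = np.array([25.0, 25, 30, 35, 40, 35, 30, 30, 35, 40, 35, 30])
_DRY_EVAP = np.array([30.0, 40, 60, 85, 110, 125, 120, 105, 75, 50, 35, 25])

_GRAZING_MONTHS = (False, False, False, False, True, True, True, True, True, True, False, False)

OBS_NOISE_SD = 1.5  # Mg C ha-1, measurement scatter added to the reference run


def _weather(rng: np.random.Generator, years: range, wet: bool) -> pd.DataFrame:
    base_rain = _WET_RAIN if wet else _DRY_RAIN
    base_evap = _WET_EVAP if wet else _DRY_EVAP
    t_base = rng.uniform(8.0, 10.0) if wet else rng.uniform(9.0, 12.0)
    sigma = 0.25 if wet else 0.12

    rows = []
    months = np.arange(1, 13)
    for year in years:
        # July-peaked sinusoidal temperature with mild monthly noise
        tmean = (
            t_base
            + 6.5 * np.cos(2.0 * np.pi * (months - 7) / 12.0)
            + rng.normal(0.0, 0.8, size=12)
        )
        rain = base_rain * np.exp(rng.normal(0.0, sigma, size=12) - sigma**2 / 2.0)
        if not wet:
            # keep the dry profile truly rain-limited in every month
            rain = np.minimum(rain, base_rain * 1.35)
        elif rain.sum() < 1010.0:
            rain *= 1010.0 / rain.sum()
        evap = base_evap * np.exp(rng.normal(0.0, 0.10, size=12) - 0.005)
        for m in range(12):
            rows.append((year, m + 1, float(tmean[m]), float(rain[m]), float(evap[m])))
    return pd.DataFrame(rows, columns=["year", "month", "tmean_c", "precip_mm", "evap_mm"])


def _grazed_management(rng: np.random.Generator, n_input: float) -> ManagementCalendar:
    stocking = float(rng.uniform(1.0, 2.0))
    # annual excreta C from grazing animals, spread over the grazing months
    excreta_c = float(rng.uniform(2.0, 3.0))
    months = [m + 1 for m, g in enumerate(_GRAZING_MONTHS) if g]
    apps = tuple(
        EOMApplication(month=m, c_amount=excreta_c / len(months), quality=DEFAULT_RUMINANT_QUALITY)
        for m in months
    )
    return ManagementCalendar(
        grazing=_GRAZING_MONTHS,
        stocking_rate=stocking,
        eom_applications=apps,
        n_input=n_input,
        above_ground_biomass=float(rng.uniform(6.0, 10.0)),
        management="grazed",
    )


def _cut_management(rng: np.random.Generator, n_input: float) -> ManagementCalendar:
    lignin = float(rng.uniform(14.0, 23.0))
    slurry = EOMQuality(
        lignin=lignin,
        holocellulose=(100.0 - lignin) / 2.0,
        solubles=(100.0 - lignin) / 2.0,
        label="cattle slurry",
    )
    slurry_c = float(rng.uniform(1.5, 2.5))
    apps = tuple(
        EOMApplication(month=m, c_amount=slurry_c / 4.0, quality=slurry)
        for m in (3, 5, 7, 8)  # after each of four cuts
    )
    return ManagementCalendar(
        grazing=(False,) * 12,
        stocking_rate=0.0,
        eom_applications=apps,
        n_input=n_input,
        above_ground_biomass=float(rng.uniform(6.0, 10.0)),
        management="cut",
    )


def generate_fixture(
    seed: int, profile: str = "wet_grazed", n_years: int = 8, start_year: int = 2004
) -> tuple[pd.DataFrame, ModelConfig, pd.DataFrame]:
    """Build (weather, config, synthetic observations) for one profile.

    The observations are the annual December SOC stocks of a reference
    RothC_3 run on the generated weather, perturbed by seeded Gaussian
    measurement noise -- they are synthetic stand-ins for field data, meant
    for exercising the evaluation machinery.
    """
    if profile not in FIXTURE_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {FIXTURE_PROFILES}")
    rng = np.random.default_rng(seed)
    wet = profile.startswith("wet")
    years = range(start_year, start_year + n_years)

    weather = _weather(rng, years, wet)

    clay = float(rng.uniform(20.0, 35.0))
    sand = float(rng.uniform(25.0, 45.0))
    site = SiteProfile(
        clay=clay,
        sand=sand,
        silt=100.0 - clay - sand,
        depth_cm=float(rng.choice([20.0, 30.0])),
        initial_soc=float(rng.uniform(64.7, 137.0)),
    )

    n_input = float(rng.uniform(183.0, 229.0))
    if profile == "wet_cut":
        management = _cut_management(rng, n_input)
    else:
        management = _grazed_management(rng, n_input)

    config = ModelConfig(
        site=site,
        management=management,
        flags=preset_flags("RothC_3"),
        seed=seed,
        label=profile,
    )

    from .simulate import run_scenario  # deferred: avoids a circular import

    reference = run_scenario(config, weather)
    obs = reference.annual.copy()
    obs["soc_mg_ha"] = obs["soc_mg_ha"] + rng.normal(0.0, OBS_NOISE_SD, size=len(obs))
    return weather, config, obs
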