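"""Scenario configuration and the RothC_0 ... RothC_4 version ladder.

A :class:`ModelConfig` bundles the site (texture, depth, initial SOC), the
management calendar (vegetation, grazing, organic amendments, fertilisation,
biomass), the four modification flags and the parameter blocks of the
individual modules.  The named presets enforce the cumulative ladder:

    RothC_0  default model (all modifications off)
    RothC_1  + ruminant excreta quality (Van Soest entry-pool partition)
    RothC_2  + three plant residue components with quality
    RothC_3  + soil water function extended to saturation
    RothC_4  + poaching damage

Arbitrary flag combinations remain available in expert mode by constructing
:class:`ModelFlags` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .eom import EOMApplication, EOMQuality
from .plants import EUROPEAN_GRASSLAND_PATTERN, PlantResidueSpec
from .poaching import PoachingParams

__all__ = [
    "ModelFlags",
    "SiteProfile",
    "ManagementCalendar",
    "ModelConfig",
    "VERSION_LADDER",
    "preset_flags",
]


@dataclass(frozen=True)
class ModelFlags:
    """Feature switches for the four grassland modifications."""

    excreta_quality: bool = False
    plant_residue: bool = False
    moisture_saturation: bool = False
    poaching: bool = False


#: Cumulative version ladder, lowest to highest.
VERSION_LADDER = ("RothC_0", "RothC_1", "RothC_2", "RothC_3", "RothC_4")

_PRESETS = {
    "RothC_0": ModelFlags(),
    "RothC_1": ModelFlags(excreta_quality=True),
    "RothC_2": ModelFlags(excreta_quality=True, plant_residue=True),
    "RothC_3": ModelFlags(excreta_quality=True, plant_residue=True, moisture_saturation=True),
    "RothC_4": ModelFlags(
        excreta_quality=True, plant_residue=True, moisture_saturation=True, poaching=True
    ),
}


def preset_flags(version: str) -> ModelFlags:
    """Flags for a named model version (``RothC_0`` .. ``RothC_4``)."""
    try:
        return _PRESETS[version]
    except KeyError:
        raise ValueError(
            f"unknown model version {version!r}; choose from {VERSION_LADDER}"
        ) from None


@dataclass(frozen=True)
class SiteProfile:
    """Soil and site descriptors of the simulated topsoil layer."""

    clay: float  # %
    sand: float  # %
    silt: float  # %
    depth_cm: float  # simulated depth, 20 or 30 cm in practice
    initial_soc: float  # Mg C ha-1 over that depth
    organic_matter: float = 2.0  # % by weight, for the water pedotransfer
    theta_override: tuple[float, float] | None = None  # measured (fc, sat)

    def __post_init__(self) -> None:
        if self.initial_soc <= 0.0:
            raise ValueError(f"initial SOC must be > 0, got {self.initial_soc}")
        if self.depth_cm <= 0.0:
            raise ValueError(f"depth must be > 0 cm, got {self.depth_cm}")


@dataclass(frozen=True)
class ManagementCalendar:
    """Monthly management plus the annual drivers of plant C input."""

    vegetated: tuple[bool, ...] = (True,) * 12
    grazing: tuple[bool, ...] = (False,) * 12
    stocking_rate: float = 0.0  # LSU ha-1 in grazing months
    eom_applications: tuple[EOMApplication, ...] = ()
    n_input: float = 0.0  # kg N ha-1 yr-1
    above_ground_biomass: float = 0.0  # Mg DM ha-1 yr-1, standing
    management: str = "grazed"  # "grazed" | "cut"
    rs_ratio_override: float | None = None
    ndf_above: float = 50.0  # %
    ndf_by_month: tuple[float, ...] | None = None
    monthly_pattern: tuple[float, ...] = tuple(EUROPEAN_GRASSLAND_PATTERN)
    legacy_dpm_rpm_ratio: float = 1.44

    def __post_init__(self) -> None:
        if len(self.vegetated) != 12 or len(self.grazing) != 12:
            raise ValueError("vegetated and grazing calendars must have 12 entries")
        if self.stocking_rate < 0.0:
            raise ValueError(f"stocking rate must be >= 0, got {self.stocking_rate}")
        if self.stocking_rate > 0.0 and not any(self.grazing):
            raise ValueError("non-zero stocking rate requires at least one grazing month")

    @property
    def any_grazing(self) -> bool:
        return any(self.grazing)

    def residue_spec(self) -> PlantResidueSpec:
        return PlantResidueSpec(
            above_ground_biomass=self.above_ground_biomass,
            management=self.management,
            n_input=self.n_input,
            rs_ratio_override=self.rs_ratio_override,
            ndf_above=self.ndf_above,
        )


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to run one scenario, minus the weather series."""

    site: SiteProfile
    management: ManagementCalendar
    flags: ModelFlags = ModelFlags()
    poaching_params: PoachingParams = PoachingParams()
    evap_is_pet: bool = False  # True if weather evap is Penman PET (factor 1.0)
    init_method: str = "pedotransfer"  # or "spinup"
    pinned_moisture_b: float | None = None  # sensitivity sweeps only
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.pinned_moisture_b is not None and not 0.2 <= self.pinned_moisture_b <= 1.0:
            raise ValueError(
                f"pinned moisture factor must lie in [0.2, 1], got {self.pinned_moisture_b}"
            )
        if self.init_method not in ("pedotransfer", "spinup"):
            raise ValueError(f"unknown init method {self.init_method!r}")

    @property
    def evap_factor(self) -> float:
        return 1.0 if self.evap_is_pet else 0.75

    def with_version(self, version: str) -> "ModelConfig":
        """Same scenario under a named model version."""
        return replace(self, flags=preset_flags(version), label=version)

    def with_swept_value(self, parameter: str, value: float) -> "ModelConfig":
        """Override one modification input for a sensitivity sweep."""
        if parameter == "moisture_factor":
            return replace(self, pinned_moisture_b=value)
        if parameter == "ndf":
            mgmt = replace(self.management, ndf_above=value, ndf_by_month=None)
            return replace(self, management=mgmt)
        if parameter == "lignin":
            rest = (100.0 - value) / 2.0
            quality = EOMQuality(
                lignin=value, holocellulose=rest, solubles=rest, label="swept"
            )
            apps = tuple(
                replace(app, quality=quality, partition_override=None)
                for app in self.management.eom_applications
            )
            mgmt = replace(self.management, eom_applications=apps)
            return replace(self, management=mgmt)
        raise ValueError(f"unknown sweep parameter {parameter!r}")
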