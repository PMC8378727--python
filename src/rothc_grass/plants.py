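"""Monthly plant-derived carbon inputs for managed grassland.

Plant residue carbon reaches the soil through three components with distinct
quality: above-ground residues, below-ground (root) residues, and
rhizodeposits.  Above-ground residue is a fixed fraction of standing
above-ground carbon (20 % when grazed; 30 % unharvested x 50 % turned over =
15 % when cut).  Below-ground biomass follows from the root:shoot ratio,
which declines exponentially with nitrogen fertilisation,

    R:S = 4.7375 * exp(-0.0043 * N_input)      [N in kg N ha-1 yr-1]

of which 50 % turns over annually as root residue; net rhizodeposition is
0.5 of root carbon and is treated as fully labile (all DPM).  Residue
quality maps neutral-detergent fibre (NDF) to the RPM entry fraction and
neutral-detergent solubles to DPM, with the below-ground fibre share raised
by ~8 percentage points of lignin; quality may vary month-on-month.

With the plant-residue modification switched off the pipeline collapses to
the classic single lumped input at DPM:RPM = 1.44.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PlantResidueSpec",
    "MonthlyCInput",
    "ComponentQuality",
    "EUROPEAN_GRASSLAND_PATTERN",
    "root_shoot_ratio",
    "annual_components",
    "component_quality",
    "distribute_monthly",
    "lumped_monthly",
]

#: Growing-season-weighted monthly input weights (Jan..Dec): a named preset
#: for temperate European grassland with a flat November-February minimum and
#: a May-June peak.  Sums to 1; user-overridable.
EUROPEAN_GRASSLAND_PATTERN = np.array(
    [0.03, 0.03, 0.08, 0.11, 0.14, 0.14, 0.12, 0.11, 0.10, 0.08, 0.03, 0.03]
)

#: DPM fraction of the classic lumped plant input (DPM:RPM = 1.44).
LEGACY_DPM_FRACTION = 1.44 / 2.44


def root_shoot_ratio(n_input: float) -> float:
    """Root:shoot biomass ratio as a function of annual N fertilisation.

    ``R:S = 4.7375 * exp(-0.0043 * n_input)``, strictly decreasing: heavier
    fertilisation shifts allocation above ground.
    """
    if not math.isfinite(n_input) or n_input < 0.0:
        raise ValueError(f"N input must be finite and >= 0, got {n_input}")
    return 4.7375 * math.exp(-0.0043 * n_input)


@dataclass(frozen=True)
class PlantResidueSpec:
    """Everything needed to turn standing biomass into annual C components."""

    above_ground_biomass: float  # Mg DM ha-1 yr-1, standing
    management: str  # "grazed" | "cut"
    n_input: float  # kg N ha-1 yr-1
    rs_ratio_override: float | None = None
    residue_fraction_above: float | None = None  # default 0.20 grazed, 0.15 cut
    root_turnover: float = 0.50
    rhizo_to_root: float = 0.50
    c_concentration: float = 0.45
    ndf_above: float = 50.0  # % of above-ground residue that is fibre
    lignin_offset_below: float = 8.0  # percentage points added to NDF below ground

    def __post_init__(self) -> None:
        if self.management not in ("grazed", "cut"):
            raise ValueError(f"management must be 'grazed' or 'cut', got {self.management!r}")
        if self.above_ground_biomass < 0.0:
            raise ValueError("above-ground biomass must be >= 0")
        for name in ("root_turnover", "rhizo_to_root", "c_concentration"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.residue_fraction_above is not None and not 0.0 <= self.residue_fraction_above <= 1.0:
            raise ValueError("residue_fraction_above must lie in [0, 1]")
        if not 0.0 <= self.ndf_above <= 100.0:
            raise ValueError(f"ndf_above must lie in [0, 100] %, got {self.ndf_above}")

    @property
    def effective_residue_fraction(self) -> float:
        if self.residue_fraction_above is not None:
            return self.residue_fraction_above
        # grazed: 20 % of standing above-ground C; cut: 30 % not harvested,
        # of which 50 % turns over annually
        return 0.20 if self.management == "grazed" else 0.30 * 0.50


@dataclass(frozen=True)
class ComponentQuality:
    """DPM/RPM entry fractions of one plant residue component."""

    f_dpm: float
    f_rpm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_dpm <= 1.0 and 0.0 <= self.f_rpm <= 1.0):
            raise ValueError(f"entry fractions must lie in [0, 1], got {self}")
        if abs(self.f_dpm + self.f_rpm - 1.0) > 1e-9:
            raise ValueError("f_dpm + f_rpm must equal 1")


def annual_components(spec: PlantResidueSpec) -> dict[str, float]:
    """Annual C of the three plant components, Mg C ha-1 yr-1.

    above  = standing above-ground C x residue fraction
    below  = root C biomass x root turnover  (root C from the R:S ratio)
    rhizo  = root C biomass x rhizodeposition-to-root ratio
    """
    above_c_biomass = spec.above_ground_biomass * spec.c_concentration
    rs = spec.rs_ratio_override
    if rs is None:
        rs = root_shoot_ratio(spec.n_input)
    below_c_biomass = above_c_biomass * rs
    return {
        "c_above": above_c_biomass * spec.effective_residue_fraction,
        "c_below": below_c_biomass * spec.root_turnover,
        "c_rhizo": below_c_biomass * spec.rhizo_to_root,
    }


def component_quality(
    ndf_above: float, lignin_offset_below: float = 8.0
) -> dict[str, ComponentQuality]:
    """Per-component DPM/RPM split from above-ground NDF (%).

    Above ground: RPM share = NDF/100.  Below ground: NDF plus the lignin
    offset.  Rhizodeposits: entirely DPM.
    """
    if not 0.0 <= ndf_above <= 100.0:
        raise ValueError(f"NDF must lie in [0, 100] %, got {ndf_above}")
    ndf_below = ndf_above + lignin_offset_below
    if not 0.0 <= ndf_below <= 100.0:
        raise ValueError(
            f"below-ground fibre share {ndf_below} % outside [0, 100] "
            f"(NDF {ndf_above} + offset {lignin_offset_below})"
        )
    return {
        "above": ComponentQuality(f_dpm=1.0 - ndf_above / 100.0, f_rpm=ndf_above / 100.0),
        "below": ComponentQuality(f_dpm=1.0 - ndf_below / 100.0, f_rpm=ndf_below / 100.0),
        "rhizo": ComponentQuality(f_dpm=1.0, f_rpm=0.0),
    }


@dataclass(frozen=True)
class MonthlyCInput:
    """Monthly plant C inputs (Mg C ha-1) with per-component entry quality.

    Arrays are indexed Jan..Dec.  ``f_dpm_*`` give the DPM share of each
    component in each month (RPM share is the complement); rhizodeposits are
    always pure DPM.
    """

    c_above: np.ndarray
    c_below: np.ndarray
    c_rhizo: np.ndarray
    f_dpm_above: np.ndarray
    f_dpm_below: np.ndarray

    def __post_init__(self) -> None:
        for name in ("c_above", "c_below", "c_rhizo", "f_dpm_above", "f_dpm_below"):
            arr = getattr(self, name)
            if np.asarray(arr).shape != (12,):
                raise ValueError(f"{name} must have shape (12,)")
        if (self.c_above < 0).any() or (self.c_below < 0).any() or (self.c_rhizo < 0).any():
            raise ValueError("monthly plant C inputs must be >= 0")

    def total_plant_c(self, month_index: int) -> float:
        return float(
            self.c_above[month_index] + self.c_below[month_index] + self.c_rhizo[month_index]
        )

    @property
    def annual_total(self) -> float:
        return float(self.c_above.sum() + self.c_below.sum() + self.c_rhizo.sum())

    def dpm_rpm_additions(self, month_index: int) -> tuple[float, float]:
        """This month's plant C split into (DPM, RPM) entry additions."""
        i = month_index
        dpm = (
            self.c_above[i] * self.f_dpm_above[i]
            + self.c_below[i] * self.f_dpm_below[i]
            + self.c_rhizo[i]
        )
        rpm = self.c_above[i] * (1.0 - self.f_dpm_above[i]) + self.c_below[i] * (
            1.0 - self.f_dpm_below[i]
        )
        return dpm, rpm

    def scaled_month(self, month_index: int, factor: float) -> "MonthlyCInput":
        """Return a copy with all plant components of one month scaled."""
        def scale(arr: np.ndarray) -> np.ndarray:
            out = arr.copy()
            out[month_index] *= factor
            return out

        return MonthlyCInput(
            c_above=scale(self.c_above),
            c_below=scale(self.c_below),
            c_rhizo=scale(self.c_rhizo),
            f_dpm_above=self.f_dpm_above,
            f_dpm_below=self.f_dpm_below,
        )


def _check_pattern(pattern: np.ndarray) -> np.ndarray:
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != (12,):
        raise ValueError("monthly pattern must have 12 weights")
    if (pattern < 0).any():
        raise ValueError("monthly pattern weights must be >= 0")
    if abs(pattern.sum() - 1.0) > 1e-9:
        raise ValueError(f"monthly pattern must sum to 1, got {pattern.sum()}")
    return pattern


def distribute_monthly(
    annual: dict[str, float],
    pattern: np.ndarray = EUROPEAN_GRASSLAND_PATTERN,
    ndf_above: float = 50.0,
    lignin_offset_below: float = 8.0,
    ndf_by_month: np.ndarray | None = None,
) -> MonthlyCInput:
    """Spread annual component C over months and attach per-month quality.

    Each component's annual carbon is multiplied by the monthly weight, so
    annual totals are conserved for any valid pattern.  If ``ndf_by_month``
    is given the DPM/RPM split is recomputed per month (month-on-month
    quality change); otherwise the single ``ndf_above`` applies throughout.
    """
    pattern = _check_pattern(pattern)
    if ndf_by_month is not None:
        ndf_series = np.asarray(ndf_by_month, dtype=float)
        if ndf_series.shape != (12,):
            raise ValueError("ndf_by_month must have 12 values")
    else:
        ndf_series = np.full(12, float(ndf_above))

    f_dpm_above = np.empty(12)
    f_dpm_below = np.empty(12)
    for i in range(12):
        q = component_quality(ndf_series[i], lignin_offset_below)
        f_dpm_above[i] = q["above"].f_dpm
        f_dpm_below[i] = q["below"].f_dpm

    return MonthlyCInput(
        c_above=annual["c_above"] * pattern,
        c_below=annual["c_below"] * pattern,
        c_rhizo=annual["c_rhizo"] * pattern,
        f_dpm_above=f_dpm_above,
        f_dpm_below=f_dpm_below,
    )


def lumped_monthly(
    annual_total_c: float,
    pattern: np.ndarray = EUROPEAN_GRASSLAND_PATTERN,
    dpm_rpm_ratio: float = 1.44,
) -> MonthlyCInput:
    """Classic single lumped plant input (legacy path, modification off).

    The whole annual plant C is carried in the above-ground slot with the
    fixed DPM:RPM split (1.44 -> 59 % DPM / 41 % RPM by default); the other
    component slots stay zero so downstream accounting is unchanged.
    """
    if annual_total_c < 0.0:
        raise ValueError("annual plant C must be >= 0")
    if dpm_rpm_ratio <= 0.0:
        raise ValueError("DPM:RPM ratio must be > 0")
    pattern = _check_pattern(pattern)
    f_dpm = dpm_rpm_ratio / (1.0 + dpm_rpm_ratio)
    zeros = np.zeros(12)
    return MonthlyCInput(
        c_above=annual_total_c * pattern,
        c_below=zeros,
        c_rhizo=zeros,
        f_dpm_above=np.full(12, f_dpm),
        f_dpm_below=zeros.copy(),
    )
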