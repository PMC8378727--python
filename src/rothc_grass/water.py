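"""Soil-moisture-deficit bookkeeping and the moisture rate-modifying factor.

The soil moisture deficit (SMD, mm) is signed here: positive values are water
missing below field capacity (the classic RothC accumulated deficit), zero is
field capacity, and negative values are excess water held between field
capacity and saturation.  The default model never goes below zero; in
saturation-extended mode the deficit may fall to ``smd_saturation`` (a
negative bound set by the texture-derived water contents), and the moisture
factor declines linearly from 1.0 at field capacity to 0.2 at saturation,
mirroring the oxygen limitation of decomposition in waterlogged soil.

Water contents at field capacity (33 kPa) and saturation come from the
Saxton & Rawls (2006) texture pedotransfer; user-measured values can be
passed directly to :class:`WaterBounds` instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "WaterBounds",
    "WaterState",
    "saxton_rawls_theta",
    "pedotransfer_water",
    "update_smd",
    "rate_modifier_moisture",
]

#: Fraction of the dry-side deficit range over which decomposition is
#: unaffected (the plateau of the reference moisture function).
DRY_PLATEAU_FRACTION = 0.444

#: Open-pan evaporation multiplier of the reference water budget.
OPEN_PAN_FACTOR = 0.75

MIN_MOISTURE_FACTOR = 0.2


@dataclass(frozen=True)
class WaterBounds:
    """Texture-derived limits of the soil water budget.

    max_smd_vegetated / max_smd_bare -- driest allowed deficit (mm, > 0)
    under growing vegetation and on bare soil respectively.
    smd_saturation -- wettest allowed deficit (mm, < 0): minus the water held
    between field capacity and saturation over the simulated depth.
    theta_fc / theta_sat -- volumetric water contents (m3 m-3).
    """

    max_smd_vegetated: float
    max_smd_bare: float
    smd_saturation: float
    theta_fc: float
    theta_sat: float
    depth_cm: float

    def __post_init__(self) -> None:
        if not self.theta_sat > self.theta_fc > 0.0:
            raise ValueError(
                f"require theta_sat > theta_fc > 0, got "
                f"theta_sat={self.theta_sat}, theta_fc={self.theta_fc}"
            )
        if not self.smd_saturation < 0.0 < self.max_smd_bare <= self.max_smd_vegetated:
            raise ValueError(
                "require smd_saturation < 0 < max_smd_bare <= max_smd_vegetated, "
                f"got {self}"
            )

    def max_smd(self, vegetated: bool) -> float:
        return self.max_smd_vegetated if vegetated else self.max_smd_bare


@dataclass(frozen=True)
class WaterState:
    """Signed soil moisture deficit, mm (positive = drier than field capacity)."""

    smd: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.smd):
            raise ValueError(f"SMD must be finite, got {self.smd}")


def saxton_rawls_theta(
    clay: float, sand: float, organic_matter: float = 2.0
) -> tuple[float, float]:
    """Volumetric water content at field capacity (33 kPa) and saturation.

    Saxton & Rawls (2006) regression on sand, clay (as %) and organic matter
    (% by weight).  Returns ``(theta_fc, theta_sat)`` in m3 m-3.
    """
    s = sand / 100.0
    c = clay / 100.0
    om = organic_matter

    t33 = (
        -0.251 * s + 0.195 * c + 0.011 * om
        + 0.006 * s * om - 0.027 * c * om + 0.452 * s * c + 0.299
    )
    theta_fc = t33 + (1.283 * t33 * t33 - 0.374 * t33 - 0.015)

    ts33 = (
        0.278 * s + 0.034 * c + 0.022 * om
        - 0.018 * s * om - 0.027 * c * om - 0.584 * s * c + 0.078
    )
    theta_s33 = ts33 + (0.636 * ts33 - 0.107)

    theta_sat = theta_fc + theta_s33 - 0.097 * s + 0.043
    return theta_fc, theta_sat


def pedotransfer_water(
    clay: float,
    sand: float,
    silt: float,
    depth_cm: float,
    organic_matter: float = 2.0,
    theta_override: tuple[float, float] | None = None,
) -> WaterBounds:
    """Build :class:`WaterBounds` from soil texture and simulated depth.

    The dry-side maximum deficit uses the reference clay polynomial scaled by
    depth, ``(20.0 + 1.3*clay - 0.01*clay**2) * depth / 23``; the bare-soil
    cap is that value divided by 1.8.  The wet-side bound is the water held
    between field capacity and saturation, ``-(theta_sat - theta_fc) * depth
    * 10`` mm.  Pass ``theta_override=(theta_fc, theta_sat)`` to bypass the
    texture pedotransfer with measured values.
    """
    total = clay + sand + silt
    if min(clay, sand, silt) < 0.0 or abs(total - 100.0) > 1.0:
        raise ValueError(
            f"texture fractions must be >= 0 and sum to 100 +/- 1 %, "
            f"got clay={clay}, sand={sand}, silt={silt} (sum {total})"
        )
    if depth_cm <= 0.0:
        raise ValueError(f"depth must be > 0 cm, got {depth_cm}")

    if theta_override is not None:
        theta_fc, theta_sat = theta_override
    else:
        theta_fc, theta_sat = saxton_rawls_theta(clay, sand, organic_matter)

    max_smd_veg = (20.0 + 1.3 * clay - 0.01 * clay * clay) * depth_cm / 23.0
    return WaterBounds(
        max_smd_vegetated=max_smd_veg,
        max_smd_bare=max_smd_veg / 1.8,
        smd_saturation=-(theta_sat - theta_fc) * depth_cm * 10.0,
        theta_fc=theta_fc,
        theta_sat=theta_sat,
        depth_cm=depth_cm,
    )


def update_smd(
    state: WaterState,
    rain: float,
    evap: float,
    vegetated: bool,
    bounds: WaterBounds,
    allow_saturation: bool,
    evap_factor: float = OPEN_PAN_FACTOR,
) -> WaterState:
    """Advance the monthly water budget.

    ``smd_new = clamp(smd + evap_factor*evap - rain, lower, upper)`` where
    ``upper`` is the applicable maximum deficit (bare cap on bare soil) and
    ``lower`` is ``smd_saturation`` in saturation-extended mode, else 0 (the
    default-model floor at field capacity).  Water beyond saturation is shed
    as instantaneous runoff by the clamp.  ``evap_factor`` is 0.75 for
    open-pan evaporation, 1.0 if the series is already potential ET.
    """
    if rain < 0.0 or evap < 0.0:
        raise ValueError(f"rain and evaporation must be >= 0, got {rain}, {evap}")
    lower = bounds.smd_saturation if allow_saturation else 0.0
    upper = bounds.max_smd(vegetated)
    smd = state.smd + evap_factor * evap - rain
    return WaterState(smd=min(max(smd, lower), upper))


def rate_modifier_moisture(
    smd: float, bounds: WaterBounds, extended: bool, vegetated: bool = True
) -> float:
    """Moisture rate-modifying factor ``b`` in [0.2, 1], continuous in SMD.

    Dry side (smd >= 0): 1.0 up to 44.4 % of the maximum deficit, then a
    linear fall to 0.2 at the maximum deficit.  Wet side (smd < 0, only
    reachable in saturation-extended mode): linear fall from 1.0 at field
    capacity to 0.2 at saturation, ``b = 1 - 0.8 * smd / smd_saturation``.
    """
    max_smd = bounds.max_smd(vegetated)
    lower = bounds.smd_saturation if extended else 0.0
    if not (lower - 1e-9 <= smd <= max_smd + 1e-9):
        raise ValueError(
            f"SMD {smd} mm outside admissible range [{lower}, {max_smd}] mm"
        )
    if smd >= 0.0:
        plateau = DRY_PLATEAU_FRACTION * max_smd
        if smd <= plateau:
            return 1.0
        frac = (max_smd - smd) / (max_smd - plateau)
        b = MIN_MOISTURE_FACTOR + (1.0 - MIN_MOISTURE_FACTOR) * frac
        return min(max(b, MIN_MOISTURE_FACTOR), 1.0)
    if not extended:
        # default mode floors the deficit at field capacity, so a (numerically
        # slightly) negative smd is at the plateau
        return 1.0
    b = 1.0 - (1.0 - MIN_MOISTURE_FACTOR) * (smd / bounds.smd_saturation)
    return min(max(b, MIN_MOISTURE_FACTOR), 1.0)
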