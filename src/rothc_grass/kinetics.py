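"""Five-pool RothC-26.3 decomposition engine.

The model partitions soil organic carbon into four active pools --
decomposable plant material (DPM), resistant plant material (RPM), microbial
biomass (BIO) and humified organic matter (HUM) -- plus inert organic matter
(IOM), which never decomposes.  Each active pool decays by first-order
kinetics on a monthly time step, with the nominal rate constant multiplied by
three dimensionless rate-modifying factors: ``a`` for air temperature, ``b``
for soil moisture and ``c`` for plant cover.  Carbon leaving a pool is split
between evolved CO2 and new BIO + HUM according to the clay content of the
soil.

All carbon amounts are stocks in Mg C ha-1 over the simulated topsoil depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CarbonState",
    "DecayConstants",
    "RateModifiers",
    "PoolAdditions",
    "DEFAULT_DECAY_CONSTANTS",
    "rate_modifier_temperature",
    "rate_modifier_cover",
    "co2_to_biohum_ratio",
    "partition_decomposed",
    "step_month",
]

#: DPM:RPM = 1.44 for improved grassland / agricultural crops, i.e. 59 % of
#: incoming plant C to DPM and 41 % to RPM.
DEFAULT_DPM_RPM_RATIO = 1.44

#: Fraction of the BIO+HUM flux that becomes microbial biomass.
BIO_SHARE = 0.46


@dataclass(frozen=True)
class DecayConstants:
    """Nominal first-order rate constants, yr-1, for the active pools."""

    k_dpm: float = 10.0
    k_rpm: float = 0.3
    k_bio: float = 0.66
    k_hum: float = 0.02

    def __post_init__(self) -> None:
        if not (self.k_dpm > self.k_bio > self.k_rpm > self.k_hum > 0.0):
            raise ValueError(
                "decay constants must satisfy k_dpm > k_bio > k_rpm > k_hum > 0, "
                f"got {self}"
            )


DEFAULT_DECAY_CONSTANTS = DecayConstants()


@dataclass(frozen=True)
class CarbonState:
    """Carbon stocks of the five pools plus the cumulative CO2 evolved.

    ``cumulative_co2`` is bookkeeping, not a soil pool: it accumulates the
    carbon respired since the start of the simulation so that mass balance
    can be audited exactly.
    """

    dpm: float
    rpm: float
    bio: float
    hum: float
    iom: float
    cumulative_co2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dpm", "rpm", "bio", "hum", "iom", "cumulative_co2"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(f"pool {name!r} must be finite and >= 0, got {v}")

    @property
    def total_soc(self) -> float:
        """Total SOC stock (active pools + IOM), Mg C ha-1."""
        return self.dpm + self.rpm + self.bio + self.hum + self.iom

    @property
    def active_soc(self) -> float:
        return self.dpm + self.rpm + self.bio + self.hum


@dataclass(frozen=True)
class RateModifiers:
    """Dimensionless multipliers on the decomposition rate constants.

    a -- temperature factor (>= 0; exceeds 1 above ~9.3 degC)
    b -- moisture factor, in [0.2, 1]
    c -- plant-cover (soil retainment) factor: 0.6 vegetated, 1.0 bare
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and self.a >= 0.0):
            raise ValueError(f"temperature factor must be >= 0, got {self.a}")
        if not 0.2 <= self.b <= 1.0:
            raise ValueError(f"moisture factor must lie in [0.2, 1], got {self.b}")
        if self.c not in (0.6, 1.0):
            raise ValueError(f"cover factor must be 0.6 or 1.0, got {self.c}")

    @property
    def product(self) -> float:
        return self.a * self.b * self.c


@dataclass(frozen=True)
class PoolAdditions:
    """Carbon entering the soil this month, already split by entry pool."""

    dpm: float = 0.0
    rpm: float = 0.0
    bio: float = 0.0
    hum: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dpm", "rpm", "bio", "hum"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(f"input to {name!r} must be finite and >= 0, got {v}")

    @property
    def total(self) -> float:
        return self.dpm + self.rpm + self.bio + self.hum


def rate_modifier_temperature(t_mean: float) -> float:
    """Temperature rate-modifying factor ``a`` from monthly mean air T (degC).

    Zero at and below -18.27 degC, then strictly increasing and continuous:
    ``a = 47.91 / (1 + exp(106.06 / (T + 18.27)))``.
    """
    if not math.isfinite(t_mean):
        raise ValueError(f"monthly mean temperature must be finite, got {t_mean}")
    if t_mean <= -18.27:
        return 0.0
    exponent = 106.06 / (t_mean + 18.27)
    if exponent > 700.0:  # exp would overflow; the factor is numerically zero
        return 0.0
    return 47.91 / (1.0 + math.exp(exponent))


def rate_modifier_cover(vegetated: bool) -> float:
    """Plant-cover factor ``c``: 0.6 under vegetation, 1.0 on bare soil."""
    return 0.6 if vegetated else 1.0


def co2_to_biohum_ratio(clay: float) -> float:
    """Ratio x = CO2 / (BIO + HUM) as a function of clay content (%).

    ``x = 1.67 * (1.85 + 1.60 * exp(-0.0786 * clay))``; decreasing in clay,
    so finer soils retain a larger share of decomposed C.
    """
    if not 0.0 <= clay <= 100.0:
        raise ValueError(f"clay content must lie in [0, 100] %, got {clay}")
    return 1.67 * (1.85 + 1.60 * math.exp(-0.0786 * clay))


def partition_decomposed(decomposed_c: float, clay: float) -> tuple[float, float, float]:
    """Split decomposed carbon into (co2, bio, hum), conserving mass exactly.

    The CO2 : (BIO + HUM) ratio is the clay function :func:`co2_to_biohum_ratio`
    and the BIO : HUM split is fixed at 46 : 54.
    """
    if not math.isfinite(decomposed_c) or decomposed_c < 0.0:
        raise ValueError(f"decomposed carbon must be >= 0, got {decomposed_c}")
    x = co2_to_biohum_ratio(clay)
    biohum = decomposed_c / (1.0 + x)
    bio = BIO_SHARE * biohum
    hum = biohum - bio
    co2 = decomposed_c - biohum
    return co2, bio, hum


def step_month(
    state: CarbonState,
    modifiers: RateModifiers,
    inputs: PoolAdditions,
    clay: float,
    constants: DecayConstants = DEFAULT_DECAY_CONSTANTS,
) -> CarbonState:
    """Advance the carbon state by one month.

    The pre-existing stock of each active pool decays analytically,
    ``P -> P * exp(-k_P * a * b * c / 12)``; the decomposed carbon is
    partitioned into CO2 / BIO / HUM by clay content; fresh inputs are then
    credited to their entry pools.  IOM is untouched.  By construction
    ``delta SOC = inputs - CO2`` holds to floating accumulation error.
    """
    rm = modifiers.product / 12.0

    decayed = {}
    decomposed_total = 0.0
    for pool, k in (
        ("dpm", constants.k_dpm),
        ("rpm", constants.k_rpm),
        ("bio", constants.k_bio),
        ("hum", constants.k_hum),
    ):
        stock = getattr(state, pool)
        remaining = stock * math.exp(-k * rm)
        decomposed_total += stock - remaining
        decayed[pool] = remaining

    co2, bio_in, hum_in = partition_decomposed(decomposed_total, clay)

    return CarbonState(
        dpm=decayed["dpm"] + inputs.dpm,
        rpm=decayed["rpm"] + inputs.rpm,
        bio=decayed["bio"] + bio_in + inputs.bio,
        hum=decayed["hum"] + hum_in + inputs.hum,
        iom=state.iom,
        cumulative_co2=state.cumulative_co2 + co2,
    )
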