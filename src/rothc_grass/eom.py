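"""Exogenous organic matter (EOM) entry-pool partitioning.

Ruminant excreta and slurry are characterized by their Van Soest fibre
fractions (lignin, holocellulose, solubles, each as % of volatile solids).
Anaerobic biodegradability B falls exponentially with lignin content, and the
applied carbon is split between the HUM, RPM and DPM entry pools:

    B   = 0.905 * exp(-0.055 * lignin)
    HUM = lignin * (1 - B)
    RPM = lignin * B + (holocellulose + solubles) * (1 - B)
    DPM = (holocellulose + solubles) * B

normalized by total volatile solids so the three fractions sum to one.  The
default (unmodified) RothC treatment of manure uses the fixed farmyard-manure
split DPM 49 % / RPM 49 % / HUM 2 % instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EOMQuality",
    "EOMPartition",
    "EOMApplication",
    "EOMSchedule",
    "FYM_PARTITION",
    "DEFAULT_RUMINANT_QUALITY",
    "biodegradability",
    "partition_eom",
    "eom_monthly_inputs",
]


@dataclass(frozen=True)
class EOMQuality:
    """Van Soest fractions of an organic amendment, % of volatile solids."""

    lignin: float
    holocellulose: float
    solubles: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("lignin", "holocellulose", "solubles"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100] % VS, got {v}")
        total = self.lignin + self.holocellulose + self.solubles
        if abs(total - 100.0) > 1.0:
            raise ValueError(
                f"Van Soest fractions must sum to 100 +/- 1 % VS, got {total}"
            )


@dataclass(frozen=True)
class EOMPartition:
    """Fractions of applied EOM carbon entering each RothC pool."""

    f_hum: float
    f_rpm: float
    f_dpm: float

    def __post_init__(self) -> None:
        for name in ("f_hum", "f_rpm", "f_dpm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(self.f_hum + self.f_rpm + self.f_dpm - 1.0) > 1e-9:
            raise ValueError(
                f"entry fractions must sum to 1, got "
                f"{self.f_hum + self.f_rpm + self.f_dpm}"
            )


#: Reference-model farmyard manure split, used when the excreta-quality
#: modification is switched off (RothC_0 behaviour).
FYM_PARTITION = EOMPartition(f_hum=0.02, f_rpm=0.49, f_dpm=0.49)

#: Shipped default ruminant excreta: lignin at the midpoint of the 9-28 % VS
#: literature interval, remainder split evenly between holocellulose and
#: solubles (only their sum enters the partition).  Data, not code --
#: override per application.
DEFAULT_RUMINANT_QUALITY = EOMQuality(
    lignin=18.5, holocellulose=40.75, solubles=40.75, label="ruminant excreta"
)


def biodegradability(lignin: float) -> float:
    """Anaerobic biodegradability B from lignin content (% VS).

    ``B = 0.905 * exp(-0.055 * lignin)``; strictly decreasing, in (0, 0.905].
    """
    if not 0.0 <= lignin <= 100.0:
        raise ValueError(f"lignin must lie in [0, 100] % VS, got {lignin}")
    return 0.905 * math.exp(-0.055 * lignin)


def partition_eom(quality: EOMQuality) -> EOMPartition:
    """Map Van Soest fractions to HUM/RPM/DPM entry fractions of applied C."""
    b = biodegradability(quality.lignin)
    labile = quality.holocellulose + quality.solubles
    hum = quality.lignin * (1.0 - b)
    rpm = quality.lignin * b + labile * (1.0 - b)
    dpm = labile * b
    total = hum + rpm + dpm  # = lignin + holocellulose + solubles
    f_hum = hum / total
    f_rpm = rpm / total
    return EOMPartition(f_hum=f_hum, f_rpm=f_rpm, f_dpm=1.0 - f_hum - f_rpm)


@dataclass(frozen=True)
class EOMApplication:
    """A single organic amendment: month (1-12), carbon amount, quality."""

    month: int
    c_amount: float
    quality: EOMQuality = DEFAULT_RUMINANT_QUALITY
    partition_override: EOMPartition | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must lie in 1..12, got {self.month}")
        if self.c_amount < 0.0:
            raise ValueError(f"applied carbon must be >= 0, got {self.c_amount}")


@dataclass(frozen=True)
class EOMSchedule:
    """Per-month EOM carbon additions to each entry pool, Mg C ha-1."""

    dpm: np.ndarray  # shape (12,)
    rpm: np.ndarray
    hum: np.ndarray

    @property
    def total(self) -> float:
        return float(self.dpm.sum() + self.rpm.sum() + self.hum.sum())


def eom_monthly_inputs(
    applications: list[EOMApplication], use_quality: bool = True
) -> EOMSchedule:
    """Build the monthly entry-pool schedule from a list of applications.

    With ``use_quality`` each application's carbon is split by its Van Soest
    partition (or an explicit ``partition_override``); otherwise the fixed
    farmyard-manure split applies to everything, reproducing the unmodified
    model.  Totals are conserved exactly.
    """
    dpm = np.zeros(12)
    rpm = np.zeros(12)
    hum = np.zeros(12)
    for app in applications:
        if use_quality:
            part = app.partition_override or partition_eom(app.quality)
        else:
            part = FYM_PARTITION
        i = app.month - 1
        dpm[i] += app.c_amount * part.f_dpm
        rpm[i] += app.c_amount * part.f_rpm
        hum[i] += app.c_amount * part.f_hum
    return EOMSchedule(dpm=dpm, rpm=rpm, hum=hum)
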