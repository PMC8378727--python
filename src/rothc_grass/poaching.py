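"""Poaching (livestock treading) damage to plant carbon inputs.

Hooves on saturated ground deform the soil surface and set back pasture
production, so the month's plant carbon input is reduced whenever grazing
coincides with soil wetter than a saturation-proximity threshold (SMD at or
below -10 mm by default).  The severity model is deliberately parametric: a
reduction linear in stocking density and capped, with all three constants
exposed in configuration.  Damage is month-local -- swards recover quickly,
so no carry-over is applied -- and manure/slurry inputs are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

from .plants import MonthlyCInput

__all__ = ["PoachingParams", "poaching_active", "input_reduction", "apply_poaching"]


@dataclass(frozen=True)
class PoachingParams:
    """Trigger threshold and severity constants of the damage model.

    smd_threshold -- SMD (mm, <= 0) at or below which soil counts as
    saturation-prone; damage_per_lsu -- fractional input reduction per
    LSU ha-1; max_reduction -- cap on the total reduction.
    """

    smd_threshold: float = -10.0
    damage_per_lsu: float = 0.10
    max_reduction: float = 0.5

    def __post_init__(self) -> None:
        if self.smd_threshold > 0.0:
            raise ValueError(f"SMD threshold must be <= 0 mm, got {self.smd_threshold}")
        if self.damage_per_lsu < 0.0:
            raise ValueError(f"damage per LSU must be >= 0, got {self.damage_per_lsu}")
        if not 0.0 <= self.max_reduction <= 1.0:
            raise ValueError(f"max reduction must lie in [0, 1], got {self.max_reduction}")


def poaching_active(smd: float, grazing_this_month: bool, params: PoachingParams) -> bool:
    """Poaching occurs iff animals are on the field and the soil is wet enough."""
    return bool(grazing_this_month) and smd <= params.smd_threshold


def input_reduction(stocking_rate: float, params: PoachingParams) -> float:
    """Fractional plant-input reduction: linear in stocking density, capped."""
    if stocking_rate < 0.0:
        raise ValueError(f"stocking rate must be >= 0 LSU ha-1, got {stocking_rate}")
    return min(params.max_reduction, params.damage_per_lsu * stocking_rate)


def apply_poaching(
    month_input: MonthlyCInput, month_index: int, active: bool, reduction: float
) -> MonthlyCInput:
    """Scale every plant component of the month by (1 - reduction) if active."""
    if not 0.0 <= reduction <= 1.0:
        raise ValueError(f"reduction must lie in [0, 1], got {reduction}")
    if not active or reduction == 0.0:
        return month_input
    return month_input.scaled_month(month_index, 1.0 - reduction)
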