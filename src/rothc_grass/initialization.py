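"""Initialization of the carbon pools from a measured total SOC stock.

The inert pool follows the Falloon relationship ``IOM = 0.049 * TOC**1.139``
(both in Mg C ha-1).  The remaining active carbon is split among DPM, RPM,
BIO and HUM using the model's own steady-state proportions: under constant
forcing with plant input split 59/41 between DPM and RPM, the flux-balance
solution of the first-order system gives pool shares that depend only on the
rate constants and the clay-driven CO2 partition,

    DPM* : RPM* : BIO* : HUM*  =  f_d/k_d : f_r/k_r
                                  : 0.46*alpha/((1-alpha)*k_b)
                                  : 0.54*alpha/((1-alpha)*k_h)

with ``alpha = 1/(1+x(clay))`` the retained fraction of decomposed carbon.
This closed form is exactly the quantity SOC/clay pedotransfer functions for
RothC are fitted to emulate, and it closes mass exactly: HUM is taken as the
residual so the five pools always sum to the measured stock.  A spin-up
variant (run to quasi-equilibrium, then rescale) is available through the
scenario runner.
"""

from __future__ import annotations

import math

from .kinetics import (
    BIO_SHARE,
    DEFAULT_DECAY_CONSTANTS,
    DEFAULT_DPM_RPM_RATIO,
    CarbonState,
    DecayConstants,
    co2_to_biohum_ratio,
)

__all__ = ["iom_falloon", "equilibrium_fractions", "init_pools"]


def iom_falloon(toc: float) -> float:
    """Inert organic matter stock from total SOC: ``0.049 * TOC**1.139``."""
    if not math.isfinite(toc) or toc < 0.0:
        raise ValueError(f"total SOC must be finite and >= 0, got {toc}")
    return 0.049 * toc**1.139


def equilibrium_fractions(
    clay: float,
    constants: DecayConstants = DEFAULT_DECAY_CONSTANTS,
    dpm_rpm_ratio: float = DEFAULT_DPM_RPM_RATIO,
) -> dict[str, float]:
    """Steady-state shares of the active pools under constant forcing.

    Independent of the input rate and of the rate-modifier product (both
    cancel), so they are a pure function of clay and the rate constants.
    """
    x = co2_to_biohum_ratio(clay)
    alpha = 1.0 / (1.0 + x)  # retained (BIO+HUM) share of decomposed C
    f_dpm = dpm_rpm_ratio / (1.0 + dpm_rpm_ratio)
    gain = alpha / (1.0 - alpha)  # total decomposition per unit fresh input, minus 1

    raw = {
        "dpm": f_dpm / constants.k_dpm,
        "rpm": (1.0 - f_dpm) / constants.k_rpm,
        "bio": BIO_SHARE * gain / constants.k_bio,
        "hum": (1.0 - BIO_SHARE) * gain / constants.k_hum,
    }
    total = sum(raw.values())
    return {pool: v / total for pool, v in raw.items()}


def init_pools(
    soc: float,
    clay: float,
    method: str = "pedotransfer",
    constants: DecayConstants = DEFAULT_DECAY_CONSTANTS,
    active_fractions: dict[str, float] | None = None,
) -> CarbonState:
    """Build a :class:`CarbonState` summing exactly to a measured SOC stock.

    ``method='pedotransfer'`` uses the closed-form equilibrium shares;
    ``method='spinup'`` expects ``active_fractions`` (shares of the active
    pools from a quasi-equilibrium run, e.g. from
    :func:`rothc_grass.simulate.spinup_fractions`) and rescales them.  In
    both cases IOM is the Falloon value and HUM is closed by residual.
    """
    iom = iom_falloon(soc)
    active = soc - iom
    if active <= 0.0:
        raise ValueError(
            f"measured SOC {soc} Mg C ha-1 does not exceed its inert fraction {iom:.3f}"
        )

    if method == "pedotransfer":
        fractions = equilibrium_fractions(clay, constants)
    elif method == "spinup":
        if active_fractions is None:
            raise ValueError("method='spinup' requires active_fractions")
        total = sum(active_fractions[p] for p in ("dpm", "rpm", "bio", "hum"))
        fractions = {p: active_fractions[p] / total for p in ("dpm", "rpm", "bio", "hum")}
    else:
        raise ValueError(f"unknown initialization method {method!r}")

    dpm = active * fractions["dpm"]
    rpm = active * fractions["rpm"]
    bio = active * fractions["bio"]
    hum = active - dpm - rpm - bio  # residual closure: pools sum to soc exactly
    if min(dpm, rpm, bio, hum) < 0.0:
        raise ValueError(
            f"pool splitting produced a negative pool for soc={soc}, clay={clay}: "
            f"dpm={dpm}, rpm={rpm}, bio={bio}, hum={hum}"
        )
    return CarbonState(dpm=dpm, rpm=rpm, bio=bio, hum=hum, iom=iom)
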