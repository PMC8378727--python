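"""File interfaces: YAML scenario configuration, CSV weather/observations,
CSV results with bit-exact round-trip.

Weather CSV columns: ``year, month, tmean_c, precip_mm, evap_mm``.
Observations CSV columns: ``year, soc_mg_ha`` (optional ``sd``).
Results CSV columns: see :data:`rothc_grass.simulate.RESULT_COLUMNS`.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import yaml

from .config import ManagementCalendar, ModelConfig, ModelFlags, SiteProfile, preset_flags
from .eom import EOMApplication, EOMPartition, EOMQuality
from .poaching import PoachingParams
from .simulate import RESULT_COLUMNS, SimulationResult

__all__ = [
    "load_weather",
    "load_observations",
    "load_config",
    "save_config",
    "write_results",
    "read_results",
]

CONFIG_SCHEMA_VERSION = 1


def load_weather(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a monthly weather CSV (contiguous months required)."""
    from .simulate import _validate_weather

    frame = pd.read_csv(path, float_precision="round_trip")
    return _validate_weather(frame)


def load_observations(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = {"year", "soc_mg_ha"} - set(frame.columns)
    if missing:
        raise ValueError(f"observations file missing columns: {sorted(missing)}")
    if frame["soc_mg_ha"].isna().any() or (frame["soc_mg_ha"] <= 0).any():
        raise ValueError("observed SOC stocks must be positive and non-missing")
    return frame


def _quality_to_dict(q: EOMQuality) -> dict:
    return {
        "lignin": q.lignin,
        "holocellulose": q.holocellulose,
        "solubles": q.solubles,
        "label": q.label,
    }


def save_config(config: ModelConfig, path: str | os.PathLike) -> None:
    """Serialize a scenario configuration to the versioned YAML schema."""
    mgmt = config.management
    doc = {
        "schema_version": CONFIG_SCHEMA_VERSION,
        "label": config.label,
        "seed": config.seed,
        "site": {
            "clay": _as_float(config.site.clay),
            "sand": _as_float(config.site.sand),
            "silt": _as_float(config.site.silt),
            "depth_cm": _as_float(config.site.depth_cm),
            "initial_soc": _as_float(config.site.initial_soc),
            "organic_matter": _as_float(config.site.organic_matter),
            "theta_override": list(config.site.theta_override)
            if config.site.theta_override
            else None,
        },
        "flags": {
            "excreta_quality": config.flags.excreta_quality,
            "plant_residue": config.flags.plant_residue,
            "moisture_saturation": config.flags.moisture_saturation,
            "poaching": config.flags.poaching,
        },
        "management": {
            "vegetated": list(mgmt.vegetated),
            "grazing": list(mgmt.grazing),
            "stocking_rate": _as_float(mgmt.stocking_rate),
            "n_input": _as_float(mgmt.n_input),
            "above_ground_biomass": _as_float(mgmt.above_ground_biomass),
            "management": mgmt.management,
            "rs_ratio_override": mgmt.rs_ratio_override,
            "ndf_above": _as_float(mgmt.ndf_above),
            "ndf_by_month": list(mgmt.ndf_by_month) if mgmt.ndf_by_month else None,
            "monthly_pattern": [float(x) for x in mgmt.monthly_pattern],
            "legacy_dpm_rpm_ratio": _as_float(mgmt.legacy_dpm_rpm_ratio),
            "eom_applications": [
                {
                    "month": app.month,
                    "c_amount": _as_float(app.c_amount),
                    "quality": _quality_to_dict(app.quality),
                    "partition_override": (
                        {
                            "f_hum": app.partition_override.f_hum,
                            "f_rpm": app.partition_override.f_rpm,
                            "f_dpm": app.partition_override.f_dpm,
                        }
                        if app.partition_override
                        else None
                    ),
                }
                for app in mgmt.eom_applications
            ],
        },
        "poaching": {
            "smd_threshold_mm": config.poaching_params.smd_threshold,
            "damage_per_lsu": config.poaching_params.damage_per_lsu,
            "max_reduction": config.poaching_params.max_reduction,
        },
        "evap_is_pet": config.evap_is_pet,
        "init_method": config.init_method,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _as_float(v) -> float:
    return float(v)


def load_config(path: str | os.PathLike, version: str | None = None) -> ModelConfig:
    """Load a scenario configuration; ``version`` overrides the flag block."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"configuration file {path} is not a mapping")
    if doc.get("schema_version") != CONFIG_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported config schema version {doc.get('schema_version')!r} "
            f"(expected {CONFIG_SCHEMA_VERSION})"
        )

    s = doc["site"]
    site = SiteProfile(
        clay=s["clay"], sand=s["sand"], silt=s["silt"], depth_cm=s["depth_cm"],
        initial_soc=s["initial_soc"], organic_matter=s.get("organic_matter", 2.0),
        theta_override=tuple(s["theta_override"]) if s.get("theta_override") else None,
    )

    m = doc["management"]
    apps = []
    for a in m.get("eom_applications", []):
        q = a["quality"]
        override = a.get("partition_override")
        apps.append(
            EOMApplication(
                month=int(a["month"]),
                c_amount=float(a["c_amount"]),
                quality=EOMQuality(
                    lignin=q["lignin"], holocellulose=q["holocellulose"],
                    solubles=q["solubles"], label=q.get("label", ""),
                ),
                partition_override=EOMPartition(**override) if override else None,
            )
        )
    management = ManagementCalendar(
        vegetated=tuple(bool(v) for v in m["vegetated"]),
        grazing=tuple(bool(v) for v in m["grazing"]),
        stocking_rate=float(m.get("stocking_rate", 0.0)),
        eom_applications=tuple(apps),
        n_input=float(m.get("n_input", 0.0)),
        above_ground_biomass=float(m.get("above_ground_biomass", 0.0)),
        management=m.get("management", "grazed"),
        rs_ratio_override=m.get("rs_ratio_override"),
        ndf_above=float(m.get("ndf_above", 50.0)),
        ndf_by_month=tuple(m["ndf_by_month"]) if m.get("ndf_by_month") else None,
        monthly_pattern=tuple(m["monthly_pattern"]),
        legacy_dpm_rpm_ratio=float(m.get("legacy_dpm_rpm_ratio", 1.44)),
    )

    if version is not None:
        flags = preset_flags(version)
    else:
        f = doc.get("flags", {})
        flags = ModelFlags(
            excreta_quality=bool(f.get("excreta_quality", False)),
            plant_residue=bool(f.get("plant_residue", False)),
            moisture_saturation=bool(f.get("moisture_saturation", False)),
            poaching=bool(f.get("poaching", False)),
        )

    p = doc.get("poaching", {})
    poaching = PoachingParams(
        smd_threshold=float(p.get("smd_threshold_mm", -10.0)),
        damage_per_lsu=float(p.get("damage_per_lsu", 0.10)),
        max_reduction=float(p.get("max_reduction", 0.5)),
    )

    return ModelConfig(
        site=site,
        management=management,
        flags=flags,
        poaching_params=poaching,
        evap_is_pet=bool(doc.get("evap_is_pet", False)),
        init_method=doc.get("init_method", "pedotransfer"),
        seed=int(doc.get("seed", 0)),
        label=doc.get("label", "") if version is None else version,
    )


def write_results(result: SimulationResult, out_dir: str | os.PathLike) -> Path:
    """Write monthly and annual result CSVs; returns the monthly file path.

    Floats are written at full ``repr`` precision so a read-back reproduces
    the series bit-exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    monthly_path = out / "results_monthly.csv"
    result.monthly.to_csv(monthly_path, index=False)
    result.annual.to_csv(out / "results_annual.csv", index=False)
    return monthly_path


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(RESULT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"results file missing columns: {sorted(missing)}")
    return frame
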