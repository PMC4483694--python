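"""Config (de)serialization and output writers.

Configs are flat YAML with units in the field names; all internal values are
in package units (mol, m3, Pa, day, K).  These helpers are the only unit /
format boundary of the package.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .exposure import DoseResponseSet, ExposureProfile
from .media import (
    ChemicalProperties,
    CompartmentSpec,
    EnvironmentSpec,
    TransportVelocities,
)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(data: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# dataclass <-> dict
# ---------------------------------------------------------------------------


def chemical_from_dict(data: Mapping[str, Any]) -> ChemicalProperties:
    fields = {f.name for f in dataclasses.fields(ChemicalProperties)}
    return ChemicalProperties(**{k: v for k, v in data.items() if k in fields})


def chemical_to_dict(chem: ChemicalProperties) -> dict:
    d = dataclasses.asdict(chem)
    d["half_life_days"] = dict(d["half_life_days"])
    return d


def environment_from_dict(data: Mapping[str, Any]) -> EnvironmentSpec:
    comps = {}
    for comp_id, spec in data["compartments"].items():
        fields = {f.name for f in dataclasses.fields(CompartmentSpec)}
        comps[comp_id] = CompartmentSpec(
            id=comp_id, **{k: v for k, v in spec.items() if k in fields and k != "id"}
        )
    transport = TransportVelocities(**data["transport"])
    areas = data["areas"]
    return EnvironmentSpec(
        compartments=comps,
        transport=transport,
        area_air_water_m2=areas["air_water_m2"],
        area_air_soil_m2=areas["air_soil_m2"],
        area_water_sediment_m2=areas["water_sediment_m2"],
        temperature_k=data.get("temperature_k", 288.15),
    )


def environment_to_dict(env: EnvironmentSpec) -> dict:
    comps = {}
    for comp_id, spec in env.compartments.items():
        d = dataclasses.asdict(spec)
        d.pop("id")
        d["phase_fractions"] = dict(d["phase_fractions"])
        comps[comp_id] = d
    return {
        "temperature_k": env.temperature_k,
        "compartments": comps,
        "areas": {
            "air_water_m2": env.area_air_water_m2,
            "air_soil_m2": env.area_air_soil_m2,
            "water_sediment_m2": env.area_water_sediment_m2,
        },
        "transport": dataclasses.asdict(env.transport),
    }


def exposure_profile_from_dict(data: Mapping[str, Any]) -> ExposureProfile:
    fields = {f.name for f in dataclasses.fields(ExposureProfile)}
    return ExposureProfile(**{k: v for k, v in data.items() if k in fields})


def dose_response_from_dict(data: Mapping[str, Any]) -> DoseResponseSet:
    fields = {f.name for f in dataclasses.fields(DoseResponseSet)}
    return DoseResponseSet(**{k: v for k, v in data.items() if k in fields})


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------


def write_concentrations_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Tidy trajectory CSV: date, compartment, fugacity_Pa, concentration, unit."""
    out = df.rename(columns={"fugacity_pa": "fugacity_Pa"})
    out.to_csv(path, index=False)


def write_risk_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Per-year risk CSV (year, R_f, R_w, R_i, R_d, R_t)."""
    out = df.rename(columns={
        "r_food": "R_f", "r_tap_water": "R_w", "r_inhalation": "R_i",
        "r_dermal": "R_d", "r_total": "R_t",
    })
    out.to_csv(path, index=False)


def write_manifest(path: str | Path, **entries: Any) -> None:
    """Run manifest: configs, seed, version, timestamp, outputs."""
    from . import __version__

    manifest = {"software": "fugrisk", "version": __version__}
    manifest.update(entries)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def write_geojson(feature_collection: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(feature_collection, fh)
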