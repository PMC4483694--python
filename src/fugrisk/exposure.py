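"""Multi-pathway exposure doses and linear cancer-risk characterization.

Doses are computed directly from compartment fugacities:

* food:     ``D_f = 1000 M Kow Z_water (f_a sum(v_k m_k) + f_w v_fish m_fish) / (rho_lp W)``
  in mg/(kg day).  Food-chain fugacity is taken equal to the air fugacity for
  terrestrial items and to the water fugacity for fish; the lipid of each item
  is at equilibrium with that fugacity through ``Z_lipid ~= Kow Z_water``.
  The factor 1000 converts g to mg.
* tap water: ``D_w = 1000 f_w Z_water M`` in ug/L (suspended solids are
  removed in treatment, so only the dissolved phase ``Z_water = 1/H`` is
  drunk; 1000 converts g/m3 to ug/L).
* inhalation: ``D_i = 1e9 f_a Z_a M`` in ng/m3 (1e9 converts g to ng).
* dermal:   ``D_d = 1000 f_a Z_a M S_a K_p / W + 1000 f_w Z_water M S_a K_p T_s / W``
  in mg/(kg day): ambient-air contact plus shower-water contact weighted by
  the shower time fraction ``T_s``.

Risks are linear: ``R = dose x slope factor (or unit risk)`` and the total is
the plain sum over the four pathways.  ``Z_a`` defaults to the bulk
(aerosol-inclusive) air capacity, since the chemical burden of air for a
particle-bound chemical is dominated by aerosol and inhalation unit risks
refer to total air concentration; a gas-only mode is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Mapping

import numpy as np
import pandas as pd

from .media import (
    ChemicalProperties,
    EnvironmentSpec,
    ParameterError,
    ZSet,
    compute_Z,
)

DOSE_UNITS = {
    "food": "mg/(kg day)",
    "tap_water": "ug/L",
    "inhalation": "ng/m3",
    "dermal": "mg/(kg day)",
}


@dataclass(frozen=True)
class ExposureProfile:
    """Average-resident exposure factors.

    ``lipid_intake_g_day`` is sum(v_k m_k) over non-fish food items (lipid
    grams ingested per day); fish is separate because its fugacity follows
    the water compartment.  ``food_origin_fraction`` scales the locally-grown
    share of the diet (1 = everything local).
    """

    lipid_intake_g_day: float = 20.0
    fish_intake_g_day: float = 30.0
    fish_lipid_fraction: float = 0.05
    lipid_density_g_m3: float = 0.9e6
    body_weight_kg: float = 60.0
    dermal_surface_area_m2: float = 1.8
    dermal_permeability_m_day: float = 7e-5
    shower_time_fraction: float = 0.0083
    food_origin_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0:
            raise ParameterError(f"body_weight_kg must be > 0, got {self.body_weight_kg!r}")
        if self.lipid_density_g_m3 <= 0:
            raise ParameterError(f"lipid_density_g_m3 must be > 0, got {self.lipid_density_g_m3!r}")
        if not 0.0 <= self.fish_lipid_fraction <= 1.0:
            raise ParameterError("fish_lipid_fraction must be in [0, 1]")
        for name in ("lipid_intake_g_day", "fish_intake_g_day",
                     "dermal_surface_area_m2", "dermal_permeability_m_day",
                     "shower_time_fraction", "food_origin_fraction"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    def replace(self, **changes) -> "ExposureProfile":
        return _dc_replace(self, **changes)


@dataclass(frozen=True)
class DoseResponseSet:
    """Linear dose-response factors.

    ``sf_food`` and ``sf_dermal`` are slope factors (per mg/(kg day));
    ``ur_water`` is the tap-water unit risk (per ug/L) and ``ur_inhalation``
    the inhalation unit risk (per ng/m3).
    """

    sf_food: float
    sf_dermal: float
    ur_water: float
    ur_inhalation: float

    def __post_init__(self) -> None:
        for name in ("sf_food", "sf_dermal", "ur_water", "ur_inhalation"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    def replace(self, **changes) -> "DoseResponseSet":
        return _dc_replace(self, **changes)


@dataclass(frozen=True)
class RiskResult:
    """Per-pathway doses and risks; ``r_total`` is their exact sum."""

    d_food: float
    d_tap_water: float
    d_inhalation: float
    d_dermal: float
    r_food: float
    r_tap_water: float
    r_inhalation: float
    r_dermal: float
    r_total: float


def _z_air(zset: ZSet, gas_only: bool) -> float:
    return zset.gas if gas_only else zset.air


def dose_food(
    f_air,
    f_water,
    chem: ChemicalProperties,
    profile: ExposureProfile,
    zset: ZSet,
):
    """Food-ingestion dose in mg/(kg day); fish at water fugacity, the rest at air."""
    lipid_conc_scale = 1000.0 * chem.molar_mass_g_mol * chem.kow * zset.water_dissolved
    intake = (
        np.asarray(f_air) * profile.lipid_intake_g_day
        + np.asarray(f_water) * profile.fish_lipid_fraction * profile.fish_intake_g_day
    )
    return (
        lipid_conc_scale * profile.food_origin_fraction * intake
        / (profile.lipid_density_g_m3 * profile.body_weight_kg)
    )


def dose_tap_water(f_water, chem: ChemicalProperties, zset: ZSet):
    """Tap-water dose metric in ug/L (dissolved phase only)."""
    return 1000.0 * np.asarray(f_water) * zset.water_dissolved * chem.molar_mass_g_mol


def dose_inhalation(
    f_air, chem: ChemicalProperties, zset: ZSet, gas_only: bool = False
):
    """Inhalation dose metric in ng/m3 (bulk, aerosol-inclusive air by default)."""
    return 1e9 * np.asarray(f_air) * _z_air(zset, gas_only) * chem.molar_mass_g_mol


def dose_dermal(
    f_air,
    f_water,
    chem: ChemicalProperties,
    profile: ExposureProfile,
    zset: ZSet,
    gas_only: bool = False,
):
    """Dermal dose in mg/(kg day): ambient air plus shower-water contact."""
    m = chem.molar_mass_g_mol
    sa_kp = profile.dermal_surface_area_m2 * profile.dermal_permeability_m_day
    air_term = 1000.0 * np.asarray(f_air) * _z_air(zset, gas_only) * m * sa_kp
    water_term = (
        1000.0 * np.asarray(f_water) * zset.water_dissolved * m
        * sa_kp * profile.shower_time_fraction
    )
    return (air_term + water_term) / profile.body_weight_kg


def characterize(
    d_food: float,
    d_tap_water: float,
    d_inhalation: float,
    d_dermal: float,
    drs: DoseResponseSet,
) -> RiskResult:
    """Linear risk characterization: four products and their unrounded sum."""
    r_f = d_food * drs.sf_food
    r_w = d_tap_water * drs.ur_water
    r_i = d_inhalation * drs.ur_inhalation
    r_d = d_dermal * drs.sf_dermal
    return RiskResult(
        d_food=d_food, d_tap_water=d_tap_water,
        d_inhalation=d_inhalation, d_dermal=d_dermal,
        r_food=r_f, r_tap_water=r_w, r_inhalation=r_i, r_dermal=r_d,
        r_total=r_f + r_w + r_i + r_d,
    )


def risk_from_fugacity(
    f_air,
    f_water,
    chem: ChemicalProperties,
    profile: ExposureProfile,
    drs: DoseResponseSet,
    zset: ZSet,
    gas_only_air: bool = False,
) -> RiskResult:
    """Full dose + risk chain for one (possibly vector) fugacity pair."""
    return characterize(
        dose_food(f_air, f_water, chem, profile, zset),
        dose_tap_water(f_water, chem, zset),
        dose_inhalation(f_air, chem, zset, gas_only_air),
        dose_dermal(f_air, f_water, chem, profile, zset, gas_only_air),
        drs,
    )


def annual_risk_table(
    dates: np.ndarray,
    f_air: np.ndarray,
    f_water: np.ndarray,
    chem: ChemicalProperties,
    env: EnvironmentSpec,
    profile: ExposureProfile,
    drs: DoseResponseSet,
    gas_only_air: bool = False,
) -> pd.DataFrame:
    """Annual-average per-pathway risks from daily fugacities.

    Because every dose is linear in fugacity, averaging daily risks equals
    evaluating risk at the annual-average fugacity; doses are computed on the
    daily grid and averaged per calendar year.
    """
    zset = compute_Z(chem, env)
    risk = risk_from_fugacity(f_air, f_water, chem, profile, drs, zset, gas_only_air)
    df = pd.DataFrame({
        "date": pd.to_datetime(dates),
        "r_food": risk.r_food,
        "r_tap_water": risk.r_tap_water,
        "r_inhalation": risk.r_inhalation,
        "r_dermal": risk.r_dermal,
        "r_total": risk.r_total,
    })
    out = df.groupby(df["date"].dt.year).mean(numeric_only=True)
    out.index.name = "year"
    return out.reset_index()
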