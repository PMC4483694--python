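"""Chemical and environmental parameters: fugacity capacities (Z) and transport
parameters (D) for a four-compartment (air, water, soil, sediment) multimedia box.

The fugacity formulation expresses the concentration of a chemical in any phase
as ``C = Z * f`` where ``f`` (Pa) is the escaping tendency shared by phases at
equilibrium and ``Z`` (mol m-3 Pa-1) is the phase's fugacity capacity.  All
transport and transformation processes are expressed as D values
(mol Pa-1 day-1) so that the flux of a process is ``D * f``.

Z parameterization (classic Mackay Level III/IV forms):

* gas phase:        ``Z = 1 / (R T)``
* dissolved water:  ``Z = 1 / H``
* sorbed solids:    ``Z = Koc * foc * rho / H``     (Koc in m3/kg, rho in kg/m3)
* aerosol:          ``Z = Kqa / (R T)`` with ``Kqa = 6e6 / P_L`` where ``P_L``
  is the (sub-cooled) liquid vapour pressure
* biota (fish):     ``Z = L * Kow / H`` with lipid fraction ``L``

Units are fixed package-wide: mol, m3, Pa, day, K.  Converters live at the
I/O boundary only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Mapping

R_GAS = 8.314  # Pa m3 / (mol K)

COMPARTMENTS = ("air", "water", "soil", "sediment")


class ParameterError(ValueError):
    """A chemical or environmental parameter is missing or out of range."""


def _require_positive(value: float, name: str) -> None:
    if value is None or not value > 0:
        raise ParameterError(f"{name} must be > 0, got {value!r}")


def _require_non_negative(value: float, name: str) -> None:
    if value is None or value < 0:
        raise ParameterError(f"{name} must be >= 0, got {value!r}")


# ---------------------------------------------------------------------------
# chemical
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChemicalProperties:
    """Physicochemical properties of one chemical.

    Parameters
    ----------
    name : str
        Chemical name (e.g. ``"benzo[a]pyrene"``).
    molar_mass_g_mol : float
        Molar mass M (g/mol).
    vapor_pressure_pa : float
        Solid (or liquid) vapour pressure at the reference temperature (Pa).
    solubility_mol_m3 : float
        Aqueous solubility at the reference temperature (mol/m3).
    henry_pa_m3_mol : float, optional
        Henry's law constant H (Pa m3/mol).  Derived as
        ``vapor_pressure / solubility`` when not given.
    log_kow : float
        log10 of the octanol-water partition coefficient.
    koc_m3_kg : float, optional
        Organic-carbon partition coefficient (m3/kg).  When absent it is
        derived by the Karickhoff rule ``Koc = 0.41 * Kow`` (L/kg), i.e.
        ``4.1e-4 * Kow`` in m3/kg.
    half_life_days : mapping
        First-order degradation half-life per compartment (days), keys
        ``air, water, soil, sediment``.  Sediment burial, when not modelled
        explicitly, is folded into the sediment half-life.
    melting_point_k : float, optional
        Melting point, used for the solid -> sub-cooled-liquid vapour
        pressure correction in the aerosol partitioning correlation.
    delta_h_henry_j_mol, delta_h_vap_j_mol : float
        Optional van't Hoff enthalpies for temperature adjustment of H and
        the vapour pressure.  Default 0 (properties constant at the
        reference temperature).
    reference_temperature_k : float
        Temperature at which the above properties are given.
    """

    name: str
    molar_mass_g_mol: float
    vapor_pressure_pa: float
    solubility_mol_m3: float
    log_kow: float
    half_life_days: Mapping[str, float]
    henry_pa_m3_mol: float | None = None
    koc_m3_kg: float | None = None
    melting_point_k: float | None = None
    delta_h_henry_j_mol: float = 0.0
    delta_h_vap_j_mol: float = 0.0
    reference_temperature_k: float = 298.15

    def __post_init__(self) -> None:
        _require_positive(self.molar_mass_g_mol, "molar_mass_g_mol")
        _require_positive(self.vapor_pressure_pa, "vapor_pressure_pa")
        _require_positive(self.solubility_mol_m3, "solubility_mol_m3")
        if self.henry_pa_m3_mol is not None:
            _require_positive(self.henry_pa_m3_mol, "henry_pa_m3_mol")
        for comp in COMPARTMENTS:
            if comp not in self.half_life_days:
                raise ParameterError(f"half_life_days missing compartment {comp!r}")
            _require_positive(self.half_life_days[comp], f"half_life_days[{comp}]")

    @property
    def kow(self) -> float:
        """Octanol-water partition coefficient on the linear scale."""
        return 10.0 ** self.log_kow

    @property
    def koc(self) -> float:
        """Organic-carbon partition coefficient (m3/kg); Karickhoff default."""
        if self.koc_m3_kg is not None:
            return self.koc_m3_kg
        return 0.41 * self.kow * 1e-3  # 0.41 Kow L/kg -> m3/kg

    def henry(self, temperature_k: float | None = None) -> float:
        """Henry's law constant (Pa m3/mol), optionally van't Hoff adjusted."""
        h = self.henry_pa_m3_mol
        if h is None:
            h = self.vapor_pressure_pa / self.solubility_mol_m3
        if temperature_k is None or self.delta_h_henry_j_mol == 0.0:
            return h
        t0 = self.reference_temperature_k
        return h * math.exp(-self.delta_h_henry_j_mol / R_GAS * (1.0 / temperature_k - 1.0 / t0))

    def liquid_vapor_pressure(self, temperature_k: float | None = None) -> float:
        """Sub-cooled liquid vapour pressure (Pa).

        For solids (melting point above the ambient temperature) the solid
        vapour pressure is converted with the standard entropy-of-fusion
        correction ``P_L = P_S * exp(6.79 * (Tm/T - 1))``.
        """
        t = self.reference_temperature_k if temperature_k is None else temperature_k
        p = self.vapor_pressure_pa
        if self.delta_h_vap_j_mol != 0.0 and temperature_k is not None:
            t0 = self.reference_temperature_k
            p = p * math.exp(-self.delta_h_vap_j_mol / R_GAS * (1.0 / t - 1.0 / t0))
        if self.melting_point_k is not None and self.melting_point_k > t:
            p = p * math.exp(6.79 * (self.melting_point_k / t - 1.0))
        return p


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompartmentSpec:
    """Geometry and phase composition of one well-mixed compartment.

    ``phase_fractions`` are volume fractions of the sub-phases and must sum
    to 1: air = {gas, aerosol}; water = {water, solids, biota}; soil =
    {solids, water, air}; sediment = {solids, water}.
    """

    id: str
    volume_m3: float
    phase_fractions: Mapping[str, float]
    solids_density_kg_m3: float = 2400.0
    organic_carbon_fraction: float = 0.02
    builtup_fraction: float = 0.0
    biota_lipid_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.id not in COMPARTMENTS:
            raise ParameterError(f"unknown compartment id {self.id!r}")
        _require_positive(self.volume_m3, f"{self.id}.volume_m3")
        total = 0.0
        for phase, frac in self.phase_fractions.items():
            _require_non_negative(frac, f"{self.id}.phase_fractions[{phase}]")
            total += frac
        if abs(total - 1.0) > 1e-6:
            raise ParameterError(
                f"{self.id}.phase_fractions must sum to 1, got {total!r}"
            )
        if not 0.0 <= self.builtup_fraction <= 1.0:
            raise ParameterError(
                f"{self.id}.builtup_fraction must be in [0, 1], got {self.builtup_fraction!r}"
            )


@dataclass(frozen=True)
class TransportVelocities:
    """Mass-transfer coefficients and flows (m/day, m3/day, dimensionless).

    The two-film air-water diffusion uses ``air_water_mtc_air_side`` and
    ``air_water_mtc_water_side``.  Particle transfer uses the dry deposition
    velocity and the rain scavenging ratio (volume of air swept per volume of
    rain).  Sediment exchange uses a suspended-solids settling velocity
    (applied to the suspended-phase Z), a resuspension velocity (applied to
    the sediment-solids Z) and a diffusive MTC.  Soil runoff velocities are
    applied to the soil water / soil solids Z.  ``irrigation_flow_m3_day``
    drives the water->soil advective transfer; ``air_exchange_cross_section_m2``
    converts wind speed into the air advective inflow/outflow G_a.
    """

    air_water_mtc_air_side_m_day: float = 72.0      # ~3 m/h
    air_water_mtc_water_side_m_day: float = 0.72    # ~0.03 m/h
    air_soil_mtc_air_side_m_day: float = 24.0       # ~1 m/h
    soil_air_diffusion_mtc_m_day: float = 0.00024   # ~1e-5 m/h, soil-side
    dry_deposition_velocity_m_day: float = 240.0    # ~10 m/h
    scavenging_ratio: float = 200000.0
    suspended_settling_velocity_m_day: float = 0.5
    sediment_resuspension_velocity_m_day: float = 1e-5
    sediment_water_diffusion_mtc_m_day: float = 0.0024  # ~1e-4 m/h
    soil_water_runoff_m_day: float = 1.0e-4
    soil_solids_runoff_m_day: float = 5.0e-8
    irrigation_flow_m3_day: float = 0.0
    air_exchange_cross_section_m2: float = 0.0
    river_flow_m3_day: float = 0.0
    wet_gas_washout: bool = True
    wet_particle_scavenging: bool = True

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if isinstance(value, bool):
                continue
            _require_non_negative(value, name)


@dataclass(frozen=True)
class EnvironmentSpec:
    """One region's physical description: four compartments plus transfer rates."""

    compartments: Mapping[str, CompartmentSpec]
    transport: TransportVelocities
    area_air_water_m2: float
    area_air_soil_m2: float
    area_water_sediment_m2: float
    temperature_k: float = 288.15

    def __post_init__(self) -> None:
        for comp in COMPARTMENTS:
            if comp not in self.compartments:
                raise ParameterError(f"compartments missing {comp!r}")
        _require_positive(self.temperature_k, "temperature_k")
        for name in ("area_air_water_m2", "area_air_soil_m2", "area_water_sediment_m2"):
            _require_non_negative(getattr(self, name), name)

    def replace(self, **changes) -> "EnvironmentSpec":
        return _dc_replace(self, **changes)


# ---------------------------------------------------------------------------
# Z values
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZSet:
    """Per-phase and bulk fugacity capacities (mol m-3 Pa-1)."""

    phases: Mapping[str, Mapping[str, float]]
    bulk: Mapping[str, float]

    @property
    def air(self) -> float:
        return self.bulk["air"]

    @property
    def water(self) -> float:
        return self.bulk["water"]

    @property
    def soil(self) -> float:
        return self.bulk["soil"]

    @property
    def sediment(self) -> float:
        return self.bulk["sediment"]

    @property
    def gas(self) -> float:
        """Gas-phase capacity 1/(RT)."""
        return self.phases["air"]["gas"]

    @property
    def water_dissolved(self) -> float:
        """Dissolved-phase capacity 1/H (the Z_water of the exposure formulas)."""
        return self.phases["water"]["water"]


def compute_Z(
    chem: ChemicalProperties,
    env: EnvironmentSpec,
    temperature_k: float | None = None,
) -> ZSet:
    """Compute per-phase and bulk fugacity capacities for the four compartments.

    The bulk capacity of a compartment is the volume-fraction weighted sum of
    its sub-phase capacities.
    """
    t = env.temperature_k if temperature_k is None else temperature_k
    _require_positive(t, "temperature_k")
    h = chem.henry(t)
    _require_positive(h, "henry_pa_m3_mol")

    z_gas = 1.0 / (R_GAS * t)
    z_diss = 1.0 / h
    p_liq = chem.liquid_vapor_pressure(t)
    kqa = 6.0e6 / p_liq  # Mackay aerosol-air partition correlation
    z_aerosol = kqa * z_gas

    def z_sorbed(comp: CompartmentSpec) -> float:
        return chem.koc * comp.organic_carbon_fraction * comp.solids_density_kg_m3 / h

    air = env.compartments["air"]
    water = env.compartments["water"]
    soil = env.compartments["soil"]
    sediment = env.compartments["sediment"]

    phases = {
        "air": {"gas": z_gas, "aerosol": z_aerosol},
        "water": {
            "water": z_diss,
            "solids": z_sorbed(water),
            "biota": water.biota_lipid_fraction * chem.kow / h,
        },
        "soil": {"solids": z_sorbed(soil), "water": z_diss, "air": z_gas},
        "sediment": {"solids": z_sorbed(sediment), "water": z_diss},
    }
    bulk = {}
    for comp_id, comp in (
        ("air", air), ("water", water), ("soil", soil), ("sediment", sediment)
    ):
        total = 0.0
        for phase, frac in comp.phase_fractions.items():
            if phase not in phases[comp_id]:
                raise ParameterError(
                    f"{comp_id}.phase_fractions has unknown phase {phase!r}"
                )
            total += frac * phases[comp_id][phase]
        bulk[comp_id] = total
    return ZSet(phases=phases, bulk=bulk)


# ---------------------------------------------------------------------------
# D values
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetRecord:
    """One day of meteorological forcing."""

    temperature_k: float
    wind_speed_m_s: float
    rain_mm_day: float
    wind_direction: str = "E"

    def __post_init__(self) -> None:
        _require_positive(self.temperature_k, "temperature_k")
        _require_non_negative(self.wind_speed_m_s, "wind_speed_m_s")
        _require_non_negative(self.rain_mm_day, "rain_mm_day")


@dataclass(frozen=True)
class DSet:
    """Transport/transformation parameters (mol Pa-1 day-1) for Eqs of motion.

    ``components`` retains the individual process contributions (diffusion,
    rain dissolution, wet/dry particle deposition, ...) for inspection.
    """

    d_aw: float
    d_wa: float
    d_aso: float
    d_soa: float
    d_wso: float
    d_sow: float
    d_wse: float
    d_sew: float
    d_reaction: Mapping[str, float]
    d_advection: Mapping[str, float]
    components: Mapping[str, float] = field(default_factory=dict)


def compute_D(
    chem: ChemicalProperties,
    env: EnvironmentSpec,
    met: MetRecord,
    zset: ZSet | None = None,
    *,
    g_air_m3_day: float | None = None,
    g_water_m3_day: float | None = None,
    wet_gas_washout: bool | None = None,
    wet_particle_scavenging: bool | None = None,
) -> DSet:
    """Populate every D value of the four-compartment mass balance.

    Process parameterization (A = interface area, U = velocity, Z = capacity):

    * two-film diffusion      ``D = A / (1/(U_air Z_gas) + 1/(U_water Z_diss))``
    * dry particle deposition ``D = A U_dry phi_aero Z_aero``
    * wet particle scavenging ``D = A U_rain Q phi_aero Z_aero`` (rain > 0 only)
    * rain (gas) dissolution  ``D = A U_rain Z_diss`` (rain > 0 only)
    * settling / resuspension ``D = A u_s phi_ss Z_ss`` / ``A u_r phi_sed Z_sed``
    * runoff                  ``D = A U_runoff Z_phase``
    * irrigation              ``D_wso = G_irr Z_diss``
    * degradation             ``D_ri = V_i Z_i ln2 / half_life_i``
    * advection               ``D_adi = G_i Z_i``

    Every air-soil interface term is scaled by ``(1 - builtup_fraction)``:
    sealed artificial surfaces remove air-soil contact.

    ``g_air_m3_day``/``g_water_m3_day`` override the advective flows; by
    default G_a = wind_speed x air_exchange_cross_section and G_w =
    river_flow.
    """
    if zset is None:
        zset = compute_Z(chem, env)
    tv = env.transport
    if wet_gas_washout is None:
        wet_gas_washout = tv.wet_gas_washout
    if wet_particle_scavenging is None:
        wet_particle_scavenging = tv.wet_particle_scavenging
    air = env.compartments["air"]
    water = env.compartments["water"]
    soil = env.compartments["soil"]
    sediment = env.compartments["sediment"]

    z_gas = zset.phases["air"]["gas"]
    z_aero = zset.phases["air"]["aerosol"]
    z_diss = zset.water_dissolved
    phi_aero = air.phase_fractions.get("aerosol", 0.0)
    phi_ss = water.phase_fractions.get("solids", 0.0)
    phi_sed_solids = sediment.phase_fractions.get("solids", 0.0)
    phi_soil_solids = soil.phase_fractions.get("solids", 0.0)

    rain_m_day = met.rain_mm_day * 1e-3
    open_soil = 1.0 - soil.builtup_fraction

    def two_film(area: float, u1: float, z1: float, u2: float, z2: float) -> float:
        # series resistance; a zero conductance on either side blocks transfer
        if area <= 0 or u1 * z1 <= 0 or u2 * z2 <= 0:
            return 0.0
        return area / (1.0 / (u1 * z1) + 1.0 / (u2 * z2))

    # --- air-water -----------------------------------------------------
    a_aw = env.area_air_water_m2
    diff_aw = two_film(
        a_aw, tv.air_water_mtc_air_side_m_day, z_gas,
        tv.air_water_mtc_water_side_m_day, z_diss,
    )
    dry_dep_w = a_aw * tv.dry_deposition_velocity_m_day * phi_aero * z_aero
    wet_part_w = (
        a_aw * rain_m_day * tv.scavenging_ratio * phi_aero * z_aero
        if wet_particle_scavenging else 0.0
    )
    rain_diss_w = a_aw * rain_m_day * z_diss if wet_gas_washout else 0.0
    d_aw = diff_aw + dry_dep_w + wet_part_w + rain_diss_w
    d_wa = diff_aw

    # --- air-soil (scaled by open, unsealed surface) --------------------
    a_as = env.area_air_soil_m2 * open_soil
    diff_as = two_film(
        a_as, tv.air_soil_mtc_air_side_m_day, z_gas,
        tv.soil_air_diffusion_mtc_m_day, z_diss,
    )
    dry_dep_s = a_as * tv.dry_deposition_velocity_m_day * phi_aero * z_aero
    wet_part_s = (
        a_as * rain_m_day * tv.scavenging_ratio * phi_aero * z_aero
        if wet_particle_scavenging else 0.0
    )
    rain_diss_s = a_as * rain_m_day * z_diss if wet_gas_washout else 0.0
    d_aso = diff_as + dry_dep_s + wet_part_s + rain_diss_s
    d_soa = diff_as

    # --- water-soil ------------------------------------------------------
    d_wso = tv.irrigation_flow_m3_day * z_diss
    a_soil = env.area_air_soil_m2  # runoff leaves through the full soil area
    d_sow = (
        a_soil * tv.soil_water_runoff_m_day * z_diss
        + a_soil * tv.soil_solids_runoff_m_day
        * phi_soil_solids * zset.phases["soil"]["solids"]
    )

    # --- water-sediment --------------------------------------------------
    a_ws = env.area_water_sediment_m2
    diff_ws = a_ws * tv.sediment_water_diffusion_mtc_m_day * z_diss
    settling = (
        a_ws * tv.suspended_settling_velocity_m_day
        * phi_ss * zset.phases["water"]["solids"]
    )
    resusp = (
        a_ws * tv.sediment_resuspension_velocity_m_day
        * phi_sed_solids * zset.phases["sediment"]["solids"]
    )
    d_wse = diff_ws + settling
    d_sew = diff_ws + resusp

    # --- degradation and advection --------------------------------------
    d_reaction = {
        comp: env.compartments[comp].volume_m3 * zset.bulk[comp]
        * math.log(2.0) / chem.half_life_days[comp]
        for comp in COMPARTMENTS
    }
    if g_air_m3_day is None:
        g_air_m3_day = met.wind_speed_m_s * 86400.0 * tv.air_exchange_cross_section_m2
    if g_water_m3_day is None:
        g_water_m3_day = tv.river_flow_m3_day
    d_advection = {
        "air": g_air_m3_day * zset.bulk["air"],
        "water": g_water_m3_day * zset.bulk["water"],
    }

    return DSet(
        d_aw=d_aw, d_wa=d_wa, d_aso=d_aso, d_soa=d_soa,
        d_wso=d_wso, d_sow=d_sow, d_wse=d_wse, d_sew=d_sew,
        d_reaction=d_reaction, d_advection=d_advection,
        components={
            "air_water_diffusion": diff_aw,
            "air_water_dry_deposition": dry_dep_w,
            "air_water_wet_scavenging": wet_part_w,
            "air_water_rain_dissolution": rain_diss_w,
            "air_soil_diffusion": diff_as,
            "air_soil_dry_deposition": dry_dep_s,
            "air_soil_wet_scavenging": wet_part_s,
            "air_soil_rain_dissolution": rain_diss_s,
            "sediment_settling": settling,
            "sediment_resuspension": resusp,
            "sediment_diffusion": diff_ws,
        },
    )
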