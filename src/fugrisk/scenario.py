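"""Packaged scenario and synthetic-data generation.

This module turns the packaged parameter set (a documented reconstruction of
an urban BaP case study: yearly emission rates 2002-2008, printed initial
fugacities and inflow concentrations, emulated daily meteorology) into the
forcing series and parameter objects the rest of the package consumes, and
runs the end-to-end chain emission -> fugacity -> concentration -> risk.

Everything is generated programmatically; nothing is downloaded.  The
meteorology generator emulates the statistical structure the analysis needs
(seasonal temperature cycle around a 15.4 degC annual mean, ~1000 mm/year of
rain in discrete events, lognormal wind speeds, season-dependent prevailing
directions) without claiming to reproduce any particular observed year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .dynamics import (
    ForcingSeries,
    FugacityTrajectory,
    annual_average,
    integrate,
    steady_state,
    to_concentrations,
)
from .exposure import DoseResponseSet, ExposureProfile, annual_risk_table
from .io import (
    chemical_from_dict,
    dose_response_from_dict,
    environment_from_dict,
    exposure_profile_from_dict,
)
from .media import ChemicalProperties, EnvironmentSpec, ParameterError
from .uncertainty import ParameterDistribution

DAYS_PER_YEAR = 365.25


def _load_packaged(name: str) -> dict:
    with resources.files("fugrisk.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ScenarioConfig:
    """Study-condition settings for the packaged scenario.

    ``emissions_mol_day`` maps year -> {air_transportation, air_industry,
    water_industry}; air emission is the transportation + industry total.
    """

    years: Sequence[int]
    seed: int
    emissions_mol_day: Mapping[int, Mapping[str, float]]
    meteorology: Mapping[str, float | Mapping[str, float]]
    initial_fugacity_pa: Sequence[float]
    inflow_concentration_mol_m3: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.years) < 1:
            raise ParameterError("scenario needs at least one year")
        for year in self.years:
            if year not in self.emissions_mol_day:
                raise ParameterError(f"emission table missing year {year}")
            for source, rate in self.emissions_mol_day[year].items():
                if rate < 0:
                    raise ParameterError(
                        f"emission {source} in {year} must be >= 0, got {rate}"
                    )


def default_config(seed: int = 0, years: Sequence[int] | None = None) -> ScenarioConfig:
    data = _load_packaged("nanjing_default.yaml")
    years = list(years) if years is not None else sorted(data["emissions_mol_day"])
    return ScenarioConfig(
        years=years,
        seed=seed,
        emissions_mol_day=data["emissions_mol_day"],
        meteorology=data["meteorology"],
        initial_fugacity_pa=list(data["initial_fugacity_pa"]),
        inflow_concentration_mol_m3=data["inflow_concentration_mol_m3"],
    )


@dataclass
class NanjingDefaults:
    """The packaged parameter bundle (chemical, region, exposure, dose-response)."""

    chem: ChemicalProperties
    env: EnvironmentSpec
    profile: ExposureProfile
    drs: DoseResponseSet
    distributions: list[ParameterDistribution]


def bap_default() -> ChemicalProperties:
    """Packaged benzo[a]pyrene physicochemical record."""
    return chemical_from_dict(_load_packaged("bap_default.yaml"))


def nanjing_default() -> NanjingDefaults:
    """Packaged regional parameter set (documented reconstruction)."""
    data = _load_packaged("nanjing_default.yaml")
    dists = [
        ParameterDistribution(
            path=d["path"], family=d["family"], group=d["group"],
            params=(d["a"], d["m"], d["b"]) if d["family"] == "triangular" else (d["m"],),
            relative=d.get("relative", False),
        )
        for d in data["distributions"]
    ]
    return NanjingDefaults(
        chem=bap_default(),
        env=environment_from_dict(data["environment"]),
        profile=exposure_profile_from_dict(data["exposure_profile"]),
        drs=dose_response_from_dict(data["dose_response"]),
        distributions=dists,
    )


# ---------------------------------------------------------------------------
# forcing synthesis
# ---------------------------------------------------------------------------


def _calendar(years: Sequence[int]) -> pd.DatetimeIndex:
    return pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")


def build_emissions(config: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    """Daily air/water emission series: yearly rates held constant in-year.

    Air total = transportation + industry; mobile sources are merged into the
    air total (no separate geometry).
    """
    dates = _calendar(config.years)
    e_air = np.empty(len(dates))
    e_water = np.empty(len(dates))
    for i, ts in enumerate(dates):
        row = config.emissions_mol_day[ts.year]
        e_air[i] = row.get("air_transportation", 0.0) + row.get("air_industry", 0.0)
        e_water[i] = row.get("water_industry", 0.0)
    return e_air, e_water


def synth_meteorology(config: ScenarioConfig, seed: int | None = None) -> pd.DataFrame:
    """Emulated daily meteorology for the scenario horizon.

    Temperature is a seasonal sinusoid around the annual mean plus Gaussian
    noise; rain is a Bernoulli occurrence with gamma-distributed intensity
    calibrated so the expected annual depth matches the configured total;
    wind speed is lognormal; wind direction is drawn from season-dependent
    prevailing-direction weights.  Leap days (Feb 29) repeat the previous
    day's weather so every year sees the same statistical forcing.
    """
    met = config.meteorology
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence([int(seed) % (2**31), 17])
    rng_t, rng_rain, rng_wind, rng_dir = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    dates = _calendar(config.years)
    doy = dates.day_of_year.to_numpy().astype(float)

    amp = float(met["seasonal_amplitude_k"])
    mean_t = float(met["annual_mean_temperature_k"])
    coldest = float(met["coldest_day_of_year"])
    temp = (
        mean_t
        - amp * np.cos(2 * np.pi * (doy - coldest) / 365.0)
        + rng_t.normal(0.0, float(met["temperature_noise_k"]), len(dates))
    )

    p_rain = float(met["rain_frequency"])
    shape = float(met["rain_gamma_shape"])
    mean_intensity = float(met["annual_rain_mm"]) / (365.0 * p_rain)
    wet = rng_rain.random(len(dates)) < p_rain
    rain = np.where(
        wet, rng_rain.gamma(shape, mean_intensity / shape, len(dates)), 0.0
    )

    wind = rng_wind.lognormal(
        math.log(float(met["wind_speed_lognormal_mean_m_s"])),
        float(met["wind_speed_lognormal_sigma"]),
        len(dates),
    )

    summer = (dates.month >= 5) & (dates.month <= 10)
    w_summer = met["direction_weights_summer"]
    w_winter = met["direction_weights_winter"]

    def draw(weights: Mapping[str, float], n: int, rng) -> np.ndarray:
        names = list(weights)
        p = np.array([weights[k] for k in names], dtype=float)
        p = p / p.sum()
        return rng.choice(names, size=n, p=p)

    direction = np.where(
        summer,
        draw(w_summer, len(dates), rng_dir),
        draw(w_winter, len(dates), rng_dir),
    )

    df = pd.DataFrame({
        "date": dates, "temperature_k": temp, "rain_mm_day": rain,
        "wind_speed_m_s": wind, "wind_direction": direction,
    })
    leap = (dates.month == 2) & (dates.day == 29)
    idx = np.flatnonzero(leap)
    for col in ("temperature_k", "rain_mm_day", "wind_speed_m_s", "wind_direction"):
        df.loc[idx, col] = df[col].to_numpy()[idx - 1]
    return df


def build_forcing(
    config: ScenarioConfig, env: EnvironmentSpec, seed: int | None = None
) -> ForcingSeries:
    """Assemble the full daily forcing series for the scenario.

    Air advective exchange G_a(t) = wind_speed x effective exchange
    cross-section; water advection G_w is the constant river through-flow.
    Background inflow concentrations are constant over the horizon.
    """
    met = synth_meteorology(config, seed)
    e_air, e_water = build_emissions(config)
    n = len(met)
    g_air = met["wind_speed_m_s"].to_numpy() * 86400.0 * env.transport.air_exchange_cross_section_m2
    return ForcingSeries(
        start_date=np.datetime64(f"{config.years[0]}-01-01"),
        e_air=e_air,
        e_water=e_water,
        g_air=g_air,
        g_water=np.full(n, env.transport.river_flow_m3_day),
        c_air=np.full(n, config.inflow_concentration_mol_m3["air"]),
        c_water=np.full(n, config.inflow_concentration_mol_m3["water"]),
        temperature_k=met["temperature_k"].to_numpy(),
        wind_speed_m_s=met["wind_speed_m_s"].to_numpy(),
        wind_direction=met["wind_direction"].to_numpy(),
        rain_mm_day=met["rain_mm_day"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# end-to-end scenario run with a named-parameter override registry
# ---------------------------------------------------------------------------

#: multiplicative override targets for one-at-a-time sensitivity analysis
SCALABLE_PARAMETERS = (
    "E_a", "E_w", "G_a", "G_w", "T", "v_aero", "S", "K_ow", "W", "SF_f",
)


@dataclass
class ScenarioResult:
    """Everything a downstream consumer needs from one scenario run."""

    chem: ChemicalProperties
    env: EnvironmentSpec
    profile: ExposureProfile
    drs: DoseResponseSet
    forcing: ForcingSeries
    trajectory: FugacityTrajectory
    concentrations: pd.DataFrame
    annual_concentrations: pd.DataFrame
    annual_risk: pd.DataFrame
    overrides: Mapping[str, float] = field(default_factory=dict)

    @property
    def mean_total_risk(self) -> float:
        """Horizon mean of the annual-average total risk."""
        return float(self.annual_risk["r_total"].mean())


def _apply_overrides(
    chem: ChemicalProperties,
    env: EnvironmentSpec,
    profile: ExposureProfile,
    drs: DoseResponseSet,
    overrides: Mapping[str, float],
):
    """Multiplicatively scale named parameters; returns modified copies."""
    import dataclasses as dc

    for name in overrides:
        if name not in SCALABLE_PARAMETERS:
            raise ParameterError(
                f"unknown override {name!r}; known: {SCALABLE_PARAMETERS}"
            )
    if "T" in overrides:
        env = env.replace(temperature_k=env.temperature_k * overrides["T"])
    if "v_aero" in overrides:
        air = env.compartments["air"]
        phi = air.phase_fractions["aerosol"] * overrides["v_aero"]
        comps = dict(env.compartments)
        comps["air"] = dc.replace(
            air, phase_fractions={"gas": 1.0 - phi, "aerosol": phi}
        )
        env = env.replace(compartments=comps)
    if "S" in overrides:
        if chem.henry_pa_m3_mol is not None:
            chem = dc.replace(
                chem, henry_pa_m3_mol=chem.henry_pa_m3_mol / overrides["S"],
                solubility_mol_m3=chem.solubility_mol_m3 * overrides["S"],
            )
        else:
            chem = dc.replace(
                chem, solubility_mol_m3=chem.solubility_mol_m3 * overrides["S"]
            )
    if "K_ow" in overrides:
        chem = dc.replace(
            chem, log_kow=chem.log_kow + math.log10(overrides["K_ow"])
        )
    if "W" in overrides:
        profile = profile.replace(
            body_weight_kg=profile.body_weight_kg * overrides["W"]
        )
    if "SF_f" in overrides:
        drs = drs.replace(sf_food=drs.sf_food * overrides["SF_f"])
    return chem, env, profile, drs


def run_scenario(
    seed: int = 0,
    years: Sequence[int] | None = None,
    overrides: Mapping[str, float] | None = None,
    defaults: NanjingDefaults | None = None,
    config: ScenarioConfig | None = None,
    integrator: str = "expm",
) -> ScenarioResult:
    """Run the full chain: forcing -> Level IV dynamics -> concentrations -> risks.

    ``overrides`` maps names from :data:`SCALABLE_PARAMETERS` to
    multiplicative factors (used by the one-at-a-time sensitivity analysis).
    """
    overrides = dict(overrides or {})
    d = defaults if defaults is not None else nanjing_default()
    chem, env, profile, drs = _apply_overrides(
        d.chem, d.env, d.profile, d.drs, overrides
    )
    cfg = config if config is not None else default_config(seed=seed, years=years)
    forcing = build_forcing(cfg, env, seed=seed)
    if "E_a" in overrides:
        forcing.e_air = forcing.e_air * overrides["E_a"]
    if "E_w" in overrides:
        forcing.e_water = forcing.e_water * overrides["E_w"]
    if "G_a" in overrides:
        forcing.g_air = forcing.g_air * overrides["G_a"]
    if "G_w" in overrides:
        forcing.g_water = forcing.g_water * overrides["G_w"]

    traj = integrate(chem, env, forcing, cfg.initial_fugacity_pa, method=integrator)
    conc = to_concentrations(traj, chem, env)
    annual_conc = annual_average(conc, allow_partial_years=True)
    annual_risk = annual_risk_table(
        forcing.dates, traj.day_mean[:, 0], traj.day_mean[:, 1],
        chem, env, profile, drs,
    )
    return ScenarioResult(
        chem=chem, env=env, profile=profile, drs=drs, forcing=forcing,
        trajectory=traj, concentrations=conc,
        annual_concentrations=annual_conc, annual_risk=annual_risk,
        overrides=overrides,
    )


def scenario_runner(
    seed: int = 0,
    years: Sequence[int] | None = None,
    defaults: NanjingDefaults | None = None,
):
    """A (overrides -> mean total risk) callable for the sensitivity module.

    The returned runner re-runs the full chain with identical forcing
    randomness (same seed) so one-at-a-time perturbations isolate the
    parameter's effect.
    """
    d = defaults if defaults is not None else nanjing_default()

    def runner(overrides: Mapping[str, float] | None = None) -> float:
        return run_scenario(
            seed=seed, years=years, overrides=overrides, defaults=d
        ).mean_total_risk

    return runner


# ---------------------------------------------------------------------------
# Monte Carlo over one year's risk
# ---------------------------------------------------------------------------


def risk_evaluator_for_year(result: ScenarioResult, year: int):
    """Build a (sampled parameters -> total risk) evaluator for one year.

    The year's mean fugacities are the point estimates; Group-1 draws enter
    as relative rescalings of those concentrations (``concentration.air``,
    ``concentration.water``), Group-2 draws replace exposure-profile fields
    (``exposure.<field>``) and Group-3 draws replace dose-response factors
    (``dose_response.<field>``) before re-evaluating the exposure/risk chain.
    """
    from .exposure import risk_from_fugacity
    from .media import compute_Z

    years = pd.to_datetime(result.forcing.dates).year
    mask = years == year
    if not mask.any():
        raise ParameterError(f"year {year} not in the simulated horizon")
    f_air = float(result.trajectory.day_mean[mask, 0].mean())
    f_water = float(result.trajectory.day_mean[mask, 1].mean())
    zset = compute_Z(result.chem, result.env)

    def evaluator(values: Mapping[str, float]) -> float:
        fa, fw = f_air, f_water
        profile, drs = result.profile, result.drs
        prof_kwargs: dict[str, float] = {}
        drs_kwargs: dict[str, float] = {}
        for path, value in values.items():
            section, _, name = path.partition(".")
            if section == "concentration":
                if name == "air":
                    fa = f_air * value
                elif name == "water":
                    fw = f_water * value
                else:
                    raise ParameterError(f"unknown concentration target {name!r}")
            elif section == "exposure":
                prof_kwargs[name] = value
            elif section == "dose_response":
                drs_kwargs[name] = value
            else:
                raise ParameterError(f"unknown parameter path {path!r}")
        if prof_kwargs:
            profile = profile.replace(**prof_kwargs)
        if drs_kwargs:
            drs = drs.replace(**drs_kwargs)
        return risk_from_fugacity(fa, fw, result.chem, profile, drs, zset).r_total

    return evaluator


def monte_carlo_for_year(
    seed: int = 0,
    year: int = 2005,
    groups: Sequence[int] = (1, 2, 3),
    n: int = 5000,
    defaults: NanjingDefaults | None = None,
    result: ScenarioResult | None = None,
):
    """Packaged Monte Carlo uncertainty analysis for one year's total risk.

    Returns ``(MonteCarloResult, point-estimate total risk)``.
    """
    from .uncertainty import monte_carlo

    d = defaults if defaults is not None else nanjing_default()
    if result is None:
        result = run_scenario(seed=seed, defaults=d)
    evaluator = risk_evaluator_for_year(result, year)
    mc = monte_carlo(evaluator, d.distributions, groups, n, seed)
    return mc, mc.point_estimate


# ---------------------------------------------------------------------------
# packaged spatial case
# ---------------------------------------------------------------------------


def run_spatial_case(
    seed: int = 0,
    years: Sequence[int] | None = None,
    wind_direction: str = "E",
    wind_speed_m_s: float = 3.0,
    mixing_height_m: float = 600.0,
    emission_district: str = "Liuhe",
    defaults: NanjingDefaults | None = None,
):
    """Linked 13-district run with a fixed wind direction.

    Emissions are placed in the configured district (the industrial-park
    district in the packaged layout); the river chain carries water
    advection; every district receives background air at the printed inflow
    concentration through its share of the external air exchange.  Returns
    ``(district risk table, GeoJSON FeatureCollection, SpatialResult)``.
    """
    from .spatial import (
        NANJING_RIVER_CHAIN,
        build_region_graph,
        external_outflows,
        map_risk,
        nanjing_districts,
        nanjing_river_links,
        run_spatial,
    )

    d = defaults if defaults is not None else nanjing_default()
    years = list(years) if years is not None else [2006]
    cfg = default_config(seed=seed, years=years)
    regions = nanjing_districts(d.env)
    graph = build_region_graph(
        regions, wind_direction, wind_speed_m_s, mixing_height_m,
        river_links=nanjing_river_links(
            regions, d.env.transport.river_flow_m3_day
        ),
    )
    met = synth_meteorology(cfg, seed)
    e_air, e_water = build_emissions(cfg)
    n_days = len(met)
    total_area = sum(r.polygon.area for r in regions)
    river_exit = NANJING_RIVER_CHAIN[-1]
    # open-boundary venting: air not handed to a downwind neighbour leaves the
    # domain; scaled daily by the wind-speed ratio to the graph's design speed
    vents = external_outflows(graph, wind_speed_m_s, mixing_height_m)
    wind_ratio = met["wind_speed_m_s"].to_numpy() / wind_speed_m_s
    forcings = []
    for idx, region in enumerate(regions):
        share = region.polygon.area / total_area
        is_source = region.name == emission_district
        g_background = (
            met["wind_speed_m_s"].to_numpy() * 86400.0
            * d.env.transport.air_exchange_cross_section_m2 * share
        )
        g_air = g_background + vents[idx] * wind_ratio
        # blended inflow concentration: only the background-exchange share of
        # g_air carries chemical in; the boundary vent admits clean air
        c_air_eff = (
            cfg.inflow_concentration_mol_m3["air"]
            * np.divide(g_background, g_air, out=np.zeros_like(g_air),
                        where=g_air > 0)
        )
        g_water = np.full(
            n_days,
            d.env.transport.river_flow_m3_day if region.name == river_exit else 0.0,
        )
        # river entry: background load enters as an equivalent emission
        entry_load = (
            d.env.transport.river_flow_m3_day
            * cfg.inflow_concentration_mol_m3["water"]
            if region.name == "Jiangning" else 0.0
        )
        forcings.append(ForcingSeries(
            start_date=np.datetime64(f"{years[0]}-01-01"),
            e_air=e_air * float(is_source),
            e_water=e_water * float(is_source) + entry_load,
            g_air=g_air,
            g_water=g_water,
            c_air=c_air_eff,
            c_water=np.full(n_days, cfg.inflow_concentration_mol_m3["water"]),
            temperature_k=met["temperature_k"].to_numpy(),
            wind_speed_m_s=met["wind_speed_m_s"].to_numpy(),
            wind_direction=met["wind_direction"].to_numpy(),
            rain_mm_day=met["rain_mm_day"].to_numpy(),
        ))
    f0 = np.tile(np.asarray(cfg.initial_fugacity_pa), (len(regions), 1))
    spatial_result = run_spatial(d.chem, graph, forcings, f0)
    table, collection = map_risk(spatial_result, d.chem, d.profile, d.drs)
    return table, collection, spatial_result


# ---------------------------------------------------------------------------
# closed-form recovery fixture
# ---------------------------------------------------------------------------


@dataclass
class RecoveryScenario:
    """Small one-region fixture with an analytically known steady state.

    Constant forcing and a D set whose air-compartment balance reduces to
    ``f* = E / D_total``, used for oracle-equivalence and parameter-recovery
    tests (invert the steady-state fugacity back to the emission rate).
    """

    chem: ChemicalProperties
    env: EnvironmentSpec
    forcing: ForcingSeries
    emission_mol_day: float

    def steady_state(self) -> np.ndarray:
        return steady_state(self.chem, self.env, self.forcing)

    def total_air_loss_d(self) -> float:
        """Total loss D value of the air compartment (mol Pa-1 day-1)."""
        from .dynamics import assemble_system
        from .media import COMPARTMENTS, compute_Z

        a, _ = assemble_system(self.chem, self.env, self.forcing, 0)
        zset = compute_Z(self.chem, self.env)
        vz = self.env.compartments["air"].volume_m3 * zset.bulk["air"]
        return -a[0, 0] * vz

    def recover_emission(self, f_air_star: float) -> float:
        """Invert ``f* = E / D_total`` for the air emission rate."""
        return f_air_star * self.total_air_loss_d()


def synth_recovery_scenario(
    seed: int = 0, emission_mol_day: float = 1.0, n_days: int = 400
) -> RecoveryScenario:
    """Build the closed-form recovery fixture.

    All cross-compartment D values vanish (no deposition, no diffusion, no
    rain), so the air compartment is a scalar linear ODE with steady state
    ``f* = E_a / (D_ra + D_ada)``.
    """
    from .media import CompartmentSpec, TransportVelocities

    chem = bap_default()
    comps = {
        "air": CompartmentSpec(
            id="air", volume_m3=1e9,
            phase_fractions={"gas": 1.0, "aerosol": 0.0},
        ),
        "water": CompartmentSpec(
            id="water", volume_m3=1e6,
            phase_fractions={"water": 1.0, "solids": 0.0, "biota": 0.0},
        ),
        "soil": CompartmentSpec(
            id="soil", volume_m3=1e5,
            phase_fractions={"solids": 0.5, "water": 0.2, "air": 0.3},
        ),
        "sediment": CompartmentSpec(
            id="sediment", volume_m3=1e4,
            phase_fractions={"solids": 0.3, "water": 0.7},
        ),
    }
    transport = TransportVelocities(
        air_water_mtc_air_side_m_day=0.0, air_water_mtc_water_side_m_day=0.0,
        air_soil_mtc_air_side_m_day=0.0, soil_air_diffusion_mtc_m_day=0.0,
        dry_deposition_velocity_m_day=0.0, scavenging_ratio=0.0,
        suspended_settling_velocity_m_day=0.0,
        sediment_resuspension_velocity_m_day=0.0,
        sediment_water_diffusion_mtc_m_day=0.0,
        soil_water_runoff_m_day=0.0, soil_solids_runoff_m_day=0.0,
        irrigation_flow_m3_day=0.0,
        air_exchange_cross_section_m2=1000.0, river_flow_m3_day=0.0,
    )
    env = EnvironmentSpec(
        compartments=comps, transport=transport,
        area_air_water_m2=0.0, area_air_soil_m2=0.0, area_water_sediment_m2=0.0,
        temperature_k=288.15,
    )
    n = n_days
    forcing = ForcingSeries(
        start_date=np.datetime64("2002-01-01"),
        e_air=np.full(n, float(emission_mol_day)), e_water=np.zeros(n),
        g_air=np.full(n, 2.0 * 86400.0 * 1000.0), g_water=np.zeros(n),
        c_air=np.zeros(n), c_water=np.zeros(n),
        temperature_k=np.full(n, 288.15), wind_speed_m_s=np.full(n, 2.0),
        wind_direction=np.array(["E"] * n), rain_mm_day=np.zeros(n),
    )
    return RecoveryScenario(
        chem=chem, env=env, forcing=forcing, emission_mol_day=emission_mol_day
    )
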