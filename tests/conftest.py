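import numpy as np
import pytest

from fugrisk import (
    CompartmentSpec,
    EnvironmentSpec,
    ForcingSeries,
    TransportVelocities,
    bap_default,
    nanjing_default,
    run_scenario,
)


@pytest.fixture(scope="session")
def bap():
    return bap_default()


@pytest.fixture(scope="session")
def defaults():
    return nanjing_default()


@pytest.fixture(scope="session")
def scenario_result(defaults):
    """Full 7-year packaged scenario run (shared: the run is deterministic)."""
    return run_scenario(seed=1, defaults=defaults)


def make_simple_env(**transport_kwargs) -> EnvironmentSpec:
    """A small, fully-specified four-compartment environment for unit tests."""
    comps = {
        "air": CompartmentSpec(
            id="air", volume_m3=1e10,
            phase_fractions={"gas": 1.0 - 2e-11, "aerosol": 2e-11},
            solids_density_kg_m3=1500.0, organic_carbon_fraction=0.0,
        ),
        "water": CompartmentSpec(
            id="water", volume_m3=1e7,
            phase_fractions={"water": 1.0 - 6e-6, "solids": 5e-6, "biota": 1e-6},
            organic_carbon_fraction=0.2,
        ),
        "soil": CompartmentSpec(
            id="soil", volume_m3=1e5,
            phase_fractions={"solids": 0.5, "water": 0.2, "air": 0.3},
            organic_carbon_fraction=0.02, builtup_fraction=0.1,
        ),
        "sediment": CompartmentSpec(
            id="sediment", volume_m3=1e4,
            phase_fractions={"solids": 0.3, "water": 0.7},
            organic_carbon_fraction=0.04,
        ),
    }
    transport = dict(
        irrigation_flow_m3_day=350.0,
        air_exchange_cross_section_m2=100.0,
        river_flow_m3_day=1e5,
    )
    transport.update(transport_kwargs)
    return EnvironmentSpec(
        compartments=comps,
        transport=TransportVelocities(**transport),
        area_air_water_m2=1e6,
        area_air_soil_m2=5e6,
        area_water_sediment_m2=1e6,
        temperature_k=288.15,
    )


@pytest.fixture
def simple_env():
    return make_simple_env()


def constant_forcing(
    n_days=10, e_air=1.0, e_water=0.1, g_air=1e6, g_water=1e5,
    c_air=0.0, c_water=0.0, rain=0.0, wind=2.0, start="2002-01-01",
) -> ForcingSeries:
    n = n_days
    return ForcingSeries(
        start_date=np.datetime64(start),
        e_air=np.full(n, float(e_air)),
        e_water=np.full(n, float(e_water)),
        g_air=np.full(n, float(g_air)),
        g_water=np.full(n, float(g_water)),
        c_air=np.full(n, float(c_air)),
        c_water=np.full(n, float(c_water)),
        temperature_k=np.full(n, 288.15),
        wind_speed_m_s=np.full(n, float(wind)),
        wind_direction=np.array(["E"] * n),
        rain_mm_day=np.full(n, float(rain)),
    )
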