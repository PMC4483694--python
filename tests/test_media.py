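"""Fugacity capacities (Z) and transport parameters (D)."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fugrisk import (
    ChemicalProperties,
    CompartmentSpec,
    MetRecord,
    ParameterError,
    compute_D,
    compute_Z,
)
from fugrisk.media import R_GAS

from conftest import make_simple_env


def met(rain=0.0, wind=2.0, temp=288.15):
    return MetRecord(temperature_k=temp, wind_speed_m_s=wind, rain_mm_day=rain)


class TestChemicalProperties:
    def test_henry_derived_from_vp_and_solubility(self, bap):
        assert bap.henry() == pytest.approx(
            bap.vapor_pressure_pa / bap.solubility_mol_m3
        )

    def test_koc_karickhoff_default(self, bap):
        # 0.41 Kow in L/kg, converted to m3/kg
        assert bap.koc == pytest.approx(0.41 * 10 ** bap.log_kow * 1e-3)

    def test_explicit_koc_wins(self, bap):
        chem = dataclasses.replace(bap, koc_m3_kg=123.0)
        assert chem.koc == 123.0

    def test_subcooled_liquid_vp_exceeds_solid_vp(self, bap):
        assert bap.liquid_vapor_pressure() > bap.vapor_pressure_pa

    @pytest.mark.parametrize("field,value", [
        ("molar_mass_g_mol", -1.0),
        ("vapor_pressure_pa", 0.0),
        ("henry_pa_m3_mol", -0.5),
    ])
    def test_invalid_parameters_raise_naming_the_field(self, bap, field, value):
        with pytest.raises(ParameterError, match=field):
            dataclasses.replace(bap, **{field: value})

    def test_missing_half_life_raises(self, bap):
        with pytest.raises(ParameterError, match="sediment"):
            dataclasses.replace(
                bap, half_life_days={"air": 1.0, "water": 1.0, "soil": 1.0}
            )


class TestComputeZ:
    def test_gas_phase_is_inverse_rt(self, bap, simple_env):
        z = compute_Z(bap, simple_env, temperature_k=298.15)
        assert z.gas == pytest.approx(1.0 / (8.314 * 298.15), rel=1e-12)
        assert z.gas == pytest.approx(4.034e-4, rel=1e-3)

    def test_dissolved_phase_vanishes_for_large_henry(self, bap, simple_env):
        volatile = dataclasses.replace(bap, henry_pa_m3_mol=1e12)
        z = compute_Z(volatile, simple_env)
        assert z.water_dissolved < 1e-11

    def test_single_phase_bulk_equals_phase_value(self, bap):
        env = make_simple_env()
        comps = dict(env.compartments)
        comps["soil"] = CompartmentSpec(
            id="soil", volume_m3=1.0, phase_fractions={"water": 1.0}
        )
        env = env.replace(compartments=comps)
        z = compute_Z(bap, env)
        assert z.bulk["soil"] == pytest.approx(z.water_dissolved, rel=1e-14)

    @given(fracs=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bulk_is_phase_weighted_sum(self, bap, fracs):
        total = sum(fracs)
        fw, fs, fb = (f / total for f in fracs)
        env = make_simple_env()
        comps = dict(env.compartments)
        comps["water"] = CompartmentSpec(
            id="water", volume_m3=1.0,
            phase_fractions={"water": fw, "solids": fs, "biota": fb},
            organic_carbon_fraction=0.2,
        )
        z = compute_Z(bap, env.replace(compartments=comps))
        expected = (
            fw * z.phases["water"]["water"]
            + fs * z.phases["water"]["solids"]
            + fb * z.phases["water"]["biota"]
        )
        assert z.bulk["water"] == pytest.approx(expected, rel=1e-14)

    def test_sorbed_exceeds_dissolved_for_hydrophobic_chemical(self, bap, simple_env):
        z = compute_Z(bap, simple_env)
        # koc foc rho / H > 1 for BaP, so sorbed-phase capacity dominates
        assert z.phases["sediment"]["solids"] > z.phases["sediment"]["water"]

    def test_nonpositive_temperature_raises(self, bap, simple_env):
        with pytest.raises(ParameterError, match="temperature"):
            compute_Z(bap, simple_env, temperature_k=0.0)

    def test_all_capacities_non_negative(self, bap, simple_env):
        z = compute_Z(bap, simple_env)
        for comp, phases in z.phases.items():
            for value in phases.values():
                assert value >= 0.0
        assert all(v >= 0 for v in z.bulk.values())


class TestComputeD:
    def test_no_rain_no_washout(self, bap, simple_env):
        d = compute_D(bap, simple_env, met(rain=0.0))
        assert d.components["air_water_wet_scavenging"] == 0.0
        assert d.components["air_water_rain_dissolution"] == 0.0
        assert d.d_aw == pytest.approx(
            d.components["air_water_diffusion"]
            + d.components["air_water_dry_deposition"]
        )

    def test_rain_activates_wet_terms(self, bap, simple_env):
        d = compute_D(bap, simple_env, met(rain=10.0))
        assert d.components["air_soil_wet_scavenging"] > 0.0
        assert d.components["air_soil_rain_dissolution"] > 0.0

    def test_wet_pathways_individually_switchable(self, bap, simple_env):
        no_gas = compute_D(bap, simple_env, met(rain=10.0), wet_gas_washout=False)
        assert no_gas.components["air_water_rain_dissolution"] == 0.0
        assert no_gas.components["air_water_wet_scavenging"] > 0.0
        no_part = compute_D(
            bap, simple_env, met(rain=10.0), wet_particle_scavenging=False
        )
        assert no_part.components["air_water_wet_scavenging"] == 0.0
        assert no_part.components["air_water_rain_dissolution"] > 0.0

    def test_half_life_doubling_halves_degradation(self, bap, simple_env):
        slow = dataclasses.replace(
            bap,
            half_life_days={k: 2 * v for k, v in bap.half_life_days.items()},
        )
        d_fast = compute_D(bap, simple_env, met())
        d_slow = compute_D(slow, simple_env, met())
        for comp in d_fast.d_reaction:
            assert d_slow.d_reaction[comp] == pytest.approx(
                d_fast.d_reaction[comp] / 2.0, rel=1e-12
            )

    def test_degradation_formula(self, bap, simple_env):
        z = compute_Z(bap, simple_env)
        d = compute_D(bap, simple_env, met(), z)
        for comp in ("air", "water", "soil", "sediment"):
            vz = simple_env.compartments[comp].volume_m3 * z.bulk[comp]
            assert d.d_reaction[comp] == pytest.approx(
                vz * math.log(2.0) / bap.half_life_days[comp], rel=1e-12
            )

    def test_fully_sealed_surface_disables_air_soil_exchange(self, bap):
        env = make_simple_env()
        comps = dict(env.compartments)
        comps["soil"] = dataclasses.replace(comps["soil"], builtup_fraction=1.0)
        d = compute_D(bap, env.replace(compartments=comps), met(rain=5.0))
        assert d.components["air_soil_diffusion"] == 0.0
        assert d.d_aso == 0.0
        assert d.d_soa == 0.0

    def test_builtup_scales_air_soil_terms_linearly(self, bap):
        d_open = compute_D(
            bap, make_simple_env(), met(rain=5.0)
        )  # builtup 0.1
        env_half = make_simple_env()
        comps = dict(env_half.compartments)
        comps["soil"] = dataclasses.replace(comps["soil"], builtup_fraction=0.55)
        d_half = compute_D(bap, env_half.replace(compartments=comps), met(rain=5.0))
        assert d_half.d_aso == pytest.approx(d_open.d_aso * 0.45 / 0.9, rel=1e-12)

    def test_irrigation_advective_transfer(self, bap, simple_env):
        # D_wso = G_irr * Z_dissolved = G_irr / H
        d = compute_D(bap, simple_env, met())
        assert d.d_wso == pytest.approx(350.0 / bap.henry(), rel=1e-12)
        env0 = make_simple_env(irrigation_flow_m3_day=0.0)
        assert compute_D(bap, env0, met()).d_wso == 0.0

    def test_advection_is_g_times_z(self, bap, simple_env):
        z = compute_Z(bap, simple_env)
        d = compute_D(bap, simple_env, met(wind=3.0))
        g_air = 3.0 * 86400.0 * 100.0
        assert d.d_advection["air"] == pytest.approx(g_air * z.bulk["air"], rel=1e-12)
        assert d.d_advection["water"] == pytest.approx(1e5 * z.bulk["water"], rel=1e-12)

    def test_explicit_flows_override_met_derived(self, bap, simple_env):
        z = compute_Z(bap, simple_env)
        d = compute_D(bap, simple_env, met(), g_air_m3_day=7.0, g_water_m3_day=11.0)
        assert d.d_advection["air"] == pytest.approx(7.0 * z.bulk["air"])
        assert d.d_advection["water"] == pytest.approx(11.0 * z.bulk["water"])

    @given(rain=st.floats(0, 50), wind=st.floats(0, 20))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_all_d_values_non_negative(self, bap, rain, wind):
        d = compute_D(bap, make_simple_env(), met(rain=rain, wind=wind))
        for name in ("d_aw", "d_wa", "d_aso", "d_soa", "d_wso", "d_sow",
                     "d_wse", "d_sew"):
            assert getattr(d, name) >= 0.0
        assert all(v >= 0 for v in d.d_reaction.values())
        assert all(v >= 0 for v in d.d_advection.values())

    def test_missing_met_field_raises(self):
        with pytest.raises(ParameterError, match="rain"):
            MetRecord(temperature_k=288.0, wind_speed_m_s=2.0, rain_mm_day=-1.0)


class TestCompartmentValidation:
    def test_phase_fractions_must_sum_to_one(self):
        with pytest.raises(ParameterError, match="sum to 1"):
            CompartmentSpec(
                id="water", volume_m3=1.0,
                phase_fractions={"water": 0.5, "solids": 0.1},
            )

    def test_builtup_fraction_bounds(self):
        with pytest.raises(ParameterError, match="builtup"):
            CompartmentSpec(
                id="soil", volume_m3=1.0,
                phase_fractions={"solids": 1.0}, builtup_fraction=1.5,
            )
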