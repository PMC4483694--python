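"""Level IV integrator, Level III steady-state oracle, unit conversions."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from fugrisk import (
    ParameterError,
    annual_average,
    assemble_system,
    integrate,
    steady_state,
    to_concentrations,
)
from fugrisk.dynamics import (
    propagate_exact,
    steady_state_of,
    system_matrices,
)
from fugrisk.media import COMPARTMENTS, DSet, compute_D, compute_Z

from conftest import constant_forcing, make_simple_env


def random_stable_system(rng, n=4):
    """Random linear box system with guaranteed losses (stable A)."""
    gains = rng.uniform(0.0, 1.0, (n, n))
    np.fill_diagonal(gains, 0.0)
    a = gains.copy()
    extra_loss = rng.uniform(0.1, 2.0, n)
    np.fill_diagonal(a, -(gains.sum(axis=0) + extra_loss))
    b = rng.uniform(0.0, 1.0, n)
    return a, b


def zero_dset():
    return DSet(
        d_aw=0, d_wa=0, d_aso=0, d_soa=0, d_wso=0, d_sow=0, d_wse=0, d_sew=0,
        d_reaction={c: 0.0 for c in COMPARTMENTS},
        d_advection={"air": 0.0, "water": 0.0},
    )


class TestSystemAssembly:
    def test_zero_processes_give_zero_matrices(self):
        a, b = system_matrices(zero_dset(), [1.0] * 4, 0, 0, 0, 0, 0, 0)
        assert np.all(a == 0.0) and np.all(b == 0.0)
        f, _ = propagate_exact(a, b, np.array([1.0, 2.0, 3.0, 4.0]), 5.0)
        np.testing.assert_allclose(f, [1.0, 2.0, 3.0, 4.0])

    def test_air_source_term(self, bap, simple_env):
        forcing = constant_forcing(e_air=2.0, g_air=1e6, c_air=1e-9)
        _, b = assemble_system(bap, simple_env, forcing, 0)
        z = compute_Z(bap, simple_env)
        vza = simple_env.compartments["air"].volume_m3 * z.bulk["air"]
        assert b[0] == pytest.approx((2.0 + 1e6 * 1e-9) / vza, rel=1e-12)

    def test_offdiagonals_are_cross_d_over_vz(self, bap, simple_env):
        forcing = constant_forcing(rain=3.0)
        a, _ = assemble_system(bap, simple_env, forcing, 0)
        z = compute_Z(bap, simple_env)
        d = compute_D(bap, simple_env, forcing.met(0), z,
                      g_air_m3_day=float(forcing.g_air[0]),
                      g_water_m3_day=float(forcing.g_water[0]))
        vz = [simple_env.compartments[c].volume_m3 * z.bulk[c] for c in COMPARTMENTS]
        # soil row: gains from air (deposition+diffusion) and water (irrigation)
        assert a[2, 0] == pytest.approx(d.d_aso / vz[2], rel=1e-12)
        assert a[2, 1] == pytest.approx(d.d_wso / vz[2], rel=1e-12)
        # sediment row: gain from water only
        assert a[3, 1] == pytest.approx(d.d_wse / vz[3], rel=1e-12)
        assert a[3, 0] == 0.0 and a[3, 2] == 0.0
        # diagonal of soil row: total soil losses
        assert a[2, 2] == pytest.approx(
            -(d.d_soa + d.d_sow + d.d_reaction["soil"]) / vz[2], rel=1e-12
        )

    def test_singular_environment_raises(self):
        with pytest.raises(ParameterError, match="V_i"):
            system_matrices(zero_dset(), [1.0, 0.0, 1.0, 1.0], 0, 0, 0, 0, 0, 0)


class TestPropagateExact:
    def test_scalar_closed_form(self):
        # df/dt = -k f + s  =>  f(t) = f* + (f0 - f*) exp(-k t)
        k, s, f0, dt = 0.7, 2.0, 5.0, 1.3
        a = np.array([[-k]])
        b = np.array([s])
        f, int_f = propagate_exact(a, b, np.array([f0]), dt)
        f_star = s / k
        assert f[0] == pytest.approx(f_star + (f0 - f_star) * math.exp(-k * dt), rel=1e-12)
        exact_int = f_star * dt + (f0 - f_star) * (1 - math.exp(-k * dt)) / k
        assert int_f[0] == pytest.approx(exact_int, rel=1e-12)

    def test_integral_matches_dense_quadrature(self):
        rng = np.random.default_rng(3)
        a, b = random_stable_system(rng)
        f0 = rng.uniform(0, 1, 4)
        _, int_f = propagate_exact(a, b, f0, 1.0)
        ts = np.linspace(0, 1.0, 2001)
        dense = np.array([propagate_exact(a, b, f0, t)[0] for t in ts])
        np.testing.assert_allclose(int_f, np.trapezoid(dense, ts, axis=0), rtol=1e-6)


class TestIntegrate:
    def test_constant_forcing_converges_to_steady_state(self, bap, simple_env):
        # shorten the half-lives so the slowest compartment converges well
        # inside the integrated horizon
        fast = dataclasses.replace(
            bap, half_life_days={k: v / 20 for k, v in bap.half_life_days.items()}
        )
        forcing = constant_forcing(n_days=3000, e_air=1.0, e_water=0.1)
        traj = integrate(fast, simple_env, forcing, [0.0] * 4)
        f_star = steady_state(fast, simple_env, forcing)
        np.testing.assert_allclose(traj.states[-1], f_star, rtol=1e-4)

    def test_single_compartment_reduction_matches_closed_form(self, bap):
        env = make_simple_env(
            air_water_mtc_air_side_m_day=0.0, air_water_mtc_water_side_m_day=0.0,
            air_soil_mtc_air_side_m_day=0.0, soil_air_diffusion_mtc_m_day=0.0,
            dry_deposition_velocity_m_day=0.0, scavenging_ratio=0.0,
            suspended_settling_velocity_m_day=0.0,
            sediment_resuspension_velocity_m_day=0.0,
            sediment_water_diffusion_mtc_m_day=0.0,
            soil_water_runoff_m_day=0.0, soil_solids_runoff_m_day=0.0,
            irrigation_flow_m3_day=0.0,
        )
        forcing = constant_forcing(n_days=50, e_air=1.0, e_water=0.0, g_water=0.0)
        traj = integrate(bap, env, forcing, [0.0] * 4)
        z = compute_Z(bap, env)
        vz = env.compartments["air"].volume_m3 * z.bulk["air"]
        d = compute_D(bap, env, forcing.met(0), z,
                      g_air_m3_day=float(forcing.g_air[0]), g_water_m3_day=0.0)
        k = (d.d_reaction["air"] + d.d_advection["air"]) / vz
        f_star = 1.0 / (d.d_reaction["air"] + d.d_advection["air"])
        t = np.arange(51, dtype=float)
        expected = f_star * (1.0 - np.exp(-k * t))
        np.testing.assert_allclose(traj.states[:, 0], expected, rtol=1e-10)

    def test_linearity_in_forcing_and_initial_state(self, bap, simple_env):
        f0 = [1e-11, 1e-10, 1e-11, 1e-10]
        one = integrate(
            bap, simple_env,
            constant_forcing(e_air=1.0, e_water=0.1, c_air=1e-9), f0,
        )
        two = integrate(
            bap, simple_env,
            constant_forcing(e_air=2.0, e_water=0.2, c_air=2e-9),
            [2 * x for x in f0],
        )
        np.testing.assert_allclose(two.states, 2.0 * one.states, rtol=1e-12)

    def test_superposition(self, bap, simple_env):
        fa = integrate(bap, simple_env, constant_forcing(e_air=1.0, e_water=0.0),
                       [1e-11, 0, 0, 0])
        fb = integrate(bap, simple_env, constant_forcing(e_air=0.0, e_water=0.5),
                       [0, 1e-10, 0, 0])
        fab = integrate(bap, simple_env, constant_forcing(e_air=1.0, e_water=0.5),
                        [1e-11, 1e-10, 0, 0])
        np.testing.assert_allclose(
            fab.states, fa.states + fb.states, rtol=1e-10, atol=1e-30
        )

    def test_non_negative_inputs_give_non_negative_states(self, bap, simple_env):
        forcing = constant_forcing(n_days=100, e_air=5.0, e_water=1.0, rain=8.0)
        traj = integrate(bap, simple_env, forcing, [0.0, 1e-3, 0.0, 0.0])
        assert np.all(traj.states >= 0.0)

    def test_bdf_matches_exact_propagation(self, bap, simple_env):
        forcing = constant_forcing(n_days=30, e_air=1.0)
        f0 = [1e-11, 1e-10, 1e-11, 1e-10]
        exact = integrate(bap, simple_env, forcing, f0, method="expm")
        stiff = integrate(bap, simple_env, forcing, f0, method="bdf",
                          rtol=1e-10, atol=1e-20)
        np.testing.assert_allclose(stiff.states, exact.states, rtol=1e-5)

    def test_mass_balance_closes(self, bap, simple_env):
        forcing = constant_forcing(n_days=200, e_air=1.0, e_water=0.2, rain=2.0)
        traj = integrate(bap, simple_env, forcing, [1e-11, 1e-10, 1e-11, 1e-10])
        assert traj.mass_balance_residual() < 1e-10

    def test_negative_initial_state_raises(self, bap, simple_env):
        with pytest.raises(ParameterError, match="non-negative"):
            integrate(bap, simple_env, constant_forcing(), [-1e-3, 0, 0, 0])


class TestSteadyState:
    def test_balance_of_source_and_loss(self):
        # single effective compartment: f* = E / D_total
        d = zero_dset()
        d = dataclasses.replace(d, d_reaction={**d.d_reaction, "air": 4.0})
        a, b = system_matrices(d, [2.0, 1.0, 1.0, 1.0], 8.0, 0, 0, 0, 0, 0)
        # other compartments have zero loss -> restrict to the air block
        f_star = -b[0] / a[0, 0]
        assert f_star == pytest.approx(8.0 / 4.0)

    def test_no_source_no_inventory(self, bap, simple_env):
        forcing = constant_forcing(e_air=0.0, e_water=0.0, c_air=0.0, c_water=0.0)
        np.testing.assert_allclose(steady_state(bap, simple_env, forcing), 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_integrator_reaches_algebraic_steady_state(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_stable_system(rng)
        f_star = steady_state_of(a, b)
        tau = 1.0 / np.abs(np.linalg.eigvals(a).real).min()
        f = rng.uniform(0, 1, 4)
        for _ in range(40):
            f, _ = propagate_exact(a, b, f, tau)
        np.testing.assert_allclose(f, f_star, rtol=1e-6)


class TestConcentrations:
    def test_zero_fugacity_zero_concentration(self, bap, simple_env):
        forcing = constant_forcing(e_air=0.0, e_water=0.0)
        traj = integrate(bap, simple_env, forcing, [0.0] * 4)
        conc = to_concentrations(traj, bap, simple_env)
        assert (conc["concentration"] == 0.0).all()

    def test_water_unit_conversion(self, bap):
        # f Z M: 1e-10 Pa x 21.7 mol/(m3 Pa) x 252.3 g/mol -> 5.47e-4 ug/L
        env = make_simple_env()
        comps = dict(env.compartments)
        comps["water"] = dataclasses.replace(
            comps["water"], phase_fractions={"water": 1.0, "solids": 0.0, "biota": 0.0}
        )
        env = env.replace(compartments=comps)
        chem = dataclasses.replace(bap, henry_pa_m3_mol=1.0 / 21.7)
        forcing = constant_forcing(n_days=2, e_air=0.0, e_water=0.0, g_water=0.0)
        traj = integrate(chem, env, forcing, [0.0, 1e-10, 0.0, 0.0])
        conc = to_concentrations(traj, chem, env, use_day_mean=False)
        w0 = conc[(conc.compartment == "water")].iloc[0]
        assert w0["concentration"] == pytest.approx(1e-10 * 21.7 * 252.3 * 1e3, rel=1e-9)
        assert w0["concentration"] == pytest.approx(5.47e-4, rel=1e-2)
        assert w0["unit"] == "ug/L"

    def test_soil_air_partitioning_grows_with_koc_foc(self, bap, simple_env):
        forcing = constant_forcing(n_days=40, e_air=1.0, rain=2.0)
        ratios = []
        for koc_scale in (1.0, 10.0):
            chem = dataclasses.replace(bap, koc_m3_kg=bap.koc * koc_scale)
            z = compute_Z(chem, simple_env)
            ratios.append(z.bulk["soil"] / z.bulk["air"])
        assert ratios[1] > ratios[0]

    def test_dry_mass_normalisation(self, bap, simple_env):
        z = compute_Z(bap, simple_env)
        forcing = constant_forcing(n_days=2, e_air=0.0, e_water=0.0, g_water=0.0)
        traj = integrate(bap, simple_env, forcing, [0.0, 0.0, 0.0, 1e-10])
        conc = to_concentrations(traj, bap, simple_env, use_day_mean=False)
        sed = conc[conc.compartment == "sediment"].iloc[0]
        spec = simple_env.compartments["sediment"]
        dry_g_m3 = spec.phase_fractions["solids"] * spec.solids_density_kg_m3 * 1e3
        expected = 1e-10 * z.bulk["sediment"] * 252.3 * 1e9 / dry_g_m3
        assert sed["concentration"] == pytest.approx(expected, rel=1e-9)


class TestAnnualAverage:
    def test_constant_series(self):
        dates = pd.date_range("2002-01-01", "2003-12-31", freq="D")
        s = pd.Series(3.5, index=dates)
        out = annual_average(s)
        assert list(out["year"]) == [2002, 2003]
        assert (out["mean"] == 3.5).all()

    def test_day_index_mean(self):
        dates = pd.date_range("2003-01-01", "2003-12-31", freq="D")
        s = pd.Series(np.arange(1, 366, dtype=float), index=dates)
        out = annual_average(s)
        assert out["mean"].iloc[0] == pytest.approx(183.0)

    def test_partial_year_raises_unless_allowed(self):
        dates = pd.date_range("2002-01-01", "2002-06-30", freq="D")
        s = pd.Series(1.0, index=dates)
        with pytest.raises(ParameterError, match="2002"):
            annual_average(s)
        out = annual_average(s, allow_partial_years=True)
        assert out["mean"].iloc[0] == 1.0

    def test_step_series_against_brute_force(self):
        dates = pd.date_range("2002-01-01", "2004-12-31", freq="D")
        rng = np.random.default_rng(11)
        values = np.repeat(rng.uniform(0, 1, 36), 31)[: len(dates)]
        s = pd.Series(values, index=dates)
        out = annual_average(s).set_index("year")["mean"]
        for year in (2002, 2003, 2004):
            mask = dates.year == year
            assert out[year] == pytest.approx(values[mask].mean(), rel=1e-12)
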