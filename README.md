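# fugrisk

Level IV multimedia fugacity modelling and multi-pathway carcinogen risk
assessment for urban regions.

`fugrisk` is for environmental modellers and exposure scientists who need to
estimate long-term human cancer risks from a persistent organic pollutant
(the packaged case: benzo[a]pyrene, BaP) when monitoring data are sparse:
the chemical's fate is *simulated* from emissions, physicochemical
properties and meteorology, and the simulated compartment fugacities feed a
multi-pathway exposure and risk chain.

## The model

Four well-mixed compartments — air, water, soil, sediment — exchange one
chemical through diffusion, deposition, runoff, resuspension, irrigation and
advection. In fugacity form (f in Pa, concentration C = Z·f, process flux =
D·f) the unsteady mass balances are linear ODEs, e.g. for air

    V_a Z_a df_a/dt = E_a + G_a c_a + f_w D_wa + f_so D_soa
                      − f_a (D_aw + D_aso + D_ra + D_ada)

and similarly for water, soil (with an irrigation gain f_w·D_wso) and
sediment. Two urbanisation-specific terms: water→soil irrigation transfer,
and reduction of all air–soil exchange by the built-up (sealed surface)
fraction. Daily forcing is propagated with the exact matrix exponential, so
mass balance closes at machine precision and stiffness is a non-issue.

Simulated fugacities drive four exposure pathways (food at air fugacity,
fish at water fugacity, tap water, inhalation, dermal) and linear risk
characterization: R_f = D_f·SF_f, …, R_t = R_f + R_w + R_i + R_d.
One-at-a-time relative sensitivity S̄ = (ΔR_t/R_t)/(Δα/α) with factors
0.9/1.1, triangular-distribution Monte Carlo in three parameter groups, and
a linked multi-district mode with wind-directed air advection complete the
chain. See `docs/methods.md` for formulas, parameter provenance and
limitations.

## Worked example

Run the packaged 2002–2008 case study (synthetic daily meteorology from the
seed; emissions, initial conditions and inflows from the packaged tables):

```python
from fugrisk import run_scenario

res = run_scenario(seed=1)
print(res.annual_concentrations.pivot(index="year", columns="compartment",
                                      values="mean").round(4))
```

```
compartment     air  sediment     soil   water
year
2002         1.9238   14.3562   1.4242  0.0248
2003         2.0143   18.3518   3.5228  0.0248
2004         2.7748   21.8914   5.3714  0.0249
2005         2.8735   25.0230   7.1311  0.0249
2006         2.4356   27.7898   9.0145  0.0249
2007         3.0400   30.2375  10.6354  0.0249
2008         3.1866   32.4061  12.1122  0.0249
```

Air is in ng/m³, water in µg/L, soil and sediment in ng/g dry weight. Soil
and sediment accumulate steadily (the chemical is lipophilic and the solid
phases are organic-rich sinks); air and water fluctuate in a narrow band set
by emissions and background inflow. Annual pathway risks:

```python
print(res.annual_risk.round(12))   # columns r_food ... r_total
```

```
 year   r_food  r_tap_water  r_inhalation  r_dermal  r_total
 2002 6.33e-02     2.30e-10      2.12e-06  7.24e-11 6.33e-02
 ...
 2008 1.05e-01     2.31e-10      3.51e-06  8.08e-11 1.05e-01
```

Food ingestion dominates by orders of magnitude (food ≫ inhalation ≫ tap
water ≈ dermal), the structural finding of this kind of assessment. The
absolute food-pathway numbers are upper-bound screening values driven by the
conservative equilibrium lipid-partitioning food model — see the methods
note's "known limitation" section before quoting them.

A 5000-draw Monte Carlo for the 2005 risk:

```python
from fugrisk.scenario import monte_carlo_for_year
from fugrisk.uncertainty import compare_point_vs_cdf

mc, _ = monte_carlo_for_year(seed=1, year=2005, n=5000)
print(compare_point_vs_cdf(mc))
# point=9.452e-02, cdf_at_point=0.518, median=9.298e-02
```

The same pipelines are available from the shell:

```sh
fugrisk simulate --seed 1 --out out/          # trajectory + concentration CSVs
fugrisk risk --seed 1 --out out/              # per-year risk CSV
fugrisk sensitivity --seed 1 --out out/       # OAT sensitivity table
fugrisk montecarlo --seed 1 --n 5000 --out out/
fugrisk spatial --seed 1 --years 2006-2006 --out out/   # 13-district GeoJSON
```

Every command writes a `manifest.json`; reruns with the same manifest inputs
are bit-identical.

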