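# Methods

## Model

`fugrisk` implements an unsteady ("Level IV") multimedia fugacity model for
one chemical in a well-mixed four-compartment region — air, surface water,
surface soil, bottom sediment — coupled to a four-pathway human exposure and
linear cancer-risk model. The state variables are the compartment fugacities
`f_i` (Pa); concentration in any phase is `C = Z f` with the fugacity
capacity `Z` (mol m⁻³ Pa⁻¹), and every transport or transformation process
is a D value (mol Pa⁻¹ day⁻¹) so its flux is `D f`. The mass balances are

```
V_a Z_a  df_a/dt  = E_a + G_a c_a + f_w D_wa + f_so D_soa − f_a (D_aw + D_aso + D_ra + D_ada)
V_w Z_w  df_w/dt  = E_w + G_w c_w + f_a D_aw + f_so D_sow + f_se D_sew
                     − f_w (D_wa + D_wso + D_wse + D_rw + D_adw)
V_so Z_so df_so/dt = f_a D_aso + f_w D_wso − f_so (D_soa + D_sow + D_rso)
V_se Z_se df_se/dt = f_w D_wse − f_se (D_sew + D_rse)
```

a linear ODE system `df/dt = A(t) f + b(t)` driven by daily emissions,
inflows and meteorology. Two features target rapidly industrialising
regions: an advective water→soil term `D_wso = G_irr / H` representing
agricultural irrigation, and scaling of **all** air–soil exchange terms by
`(1 − builtup_fraction)`, since sealed artificial surfaces remove air–soil
contact (deposition onto pavement is routed to drains, not to the soil
column, so the scaling is applied to the deposition terms as well as to
diffusion).

### Z and D parameterization

Standard Mackay forms: `Z_gas = 1/RT`; `Z_dissolved = 1/H`;
`Z_sorbed = Koc · foc · ρ_solids / H` (Koc defaults to the Karickhoff rule
0.41 Kow L/kg); `Z_aerosol = (6×10⁶ / P_L) / RT` with the sub-cooled liquid
vapour pressure from the entropy-of-fusion correction
`P_L = P_S · exp(6.79 (Tm/T − 1))`; `Z_fish = L_lipid · Kow / H`. Bulk Z is
the volume-fraction weighted sum of sub-phase Z. D values: two-film
diffusion `A / (1/(U₁Z₁) + 1/(U₂Z₂))` (zero conductance on either side
blocks transfer); dry particle deposition `A U_dry φ_aero Z_aero`; wet
particle scavenging `A U_rain Q φ_aero Z_aero`; rain gas dissolution
`A U_rain Z_dissolved`; suspended-solids settling, sediment resuspension and
runoff as velocity × phase-Z products; degradation `V Z ln2 / t½`;
advection `G Z`. Wet gas washout and wet particle scavenging are
individually switchable; the packaged scenario disables gas washout on the
grounds that the chemical is predominantly aerosol-bound and gas-phase
rain equilibration is kinetically limited. Sediment burial is not modelled
separately; it is folded into the sediment half-life.

Temperature dependence of H and the vapour pressure is available as a van't
Hoff form with configurable enthalpies but defaults to constants at the
reference temperature, and Z values are evaluated once at the environment
reference temperature for a run; daily meteorology enters through rain
(wet deposition), wind (air advection) only.

### Integration

Forcing is held piecewise-constant per day, so each day is propagated with
the exact matrix exponential in Van Loan block form, which simultaneously
yields the exact within-day integral of `f`. Consequences: the integrator
is unconditionally stable regardless of the orders-of-magnitude spread
between the air and sediment time constants, daily means are exact, and the
integrated mass balance (inventory change = sources − degradation −
advective losses, inter-compartment transfers cancelling) closes at
machine precision — the flux-quadrature audit in the tests typically shows
residuals ~10⁻¹⁴. A BDF (`scipy.integrate.solve_ivp`) path with rtol 10⁻⁸
/ atol 10⁻¹⁸ Pa is retained and cross-checked against the exact propagator.
Fugacities more negative than 10⁻¹⁵ Pa raise an error (a bad parameter set,
not numerical wobble); smaller negatives are clipped to zero. The algebraic
steady state (`A f + b = 0`, the "Level III" solution) is used throughout
the tests as an independent oracle for the integrator.

### Exposure and risk

Doses follow the fugacity-form pathway equations: food (all terrestrial
items at the air fugacity, fish at the water fugacity, lipid at equilibrium
via `Z_lipid ≈ Kow Z_water`), tap water (dissolved phase only — treatment
removes suspended solids), inhalation (bulk, aerosol-inclusive air by
default, since the burden of particle-bound chemical dominates and unit
risks refer to total air concentration; gas-only by flag), and dermal
(ambient air plus shower water weighted by the shower-time fraction). The
numeric factors 1000 and 10⁹ in the dose formulas are pure unit conversions
(g→mg, g→ng). Risks are linear — slope factors for the mg/(kg·day)
pathways, unit risks for the concentration metrics — and total risk is the
exact sum of the four pathways. Every dose is linear in fugacity, so
annual-average risks equal risks at annual-average fugacity; doses are
computed daily and averaged per calendar year. The locally-grown food share
is an explicit parameter defaulting to 1 (all local produce consumed
locally, imports clean).

### Sensitivity and uncertainty

One-at-a-time relative sensitivity `S̄ = (ΔR_t/R_t)/(Δα/α)` from full model
re-runs at α×0.9 and α×1.1, reported in percent; the scalar output is the
horizon mean of the annual total risk. Monte Carlo propagation uses
triangular distributions in three groups: group 1 (environmental and
physicochemical) enters as triangular `(0.5α, α, 1.5α)` rescalings of the
point-estimate concentrations — the fate model is not re-integrated per
draw, which both matches the intended procedure and sidesteps the mutual
correlation of group-1 parameters; groups 2 (exposure) and 3
(dose–response) re-evaluate the exposure/risk algebra per draw. One master
seed is split into per-parameter substreams (`numpy` SeedSequence), making
runs bit-reproducible. The packaged example analyses the 2005 food-ingestion
risk with 5000 draws per group combination.

### Spatial multi-box mode

Districts are full four-compartment boxes coupled by directed advective
links: air links are created between adjacent polygons when the wind motion
vector points from one centroid toward the other, with flow = wind speed ×
shared boundary length × mixing height × |cos θ| (default mixing height
1000 m; 600 m in the packaged case); water links follow the river topology
regardless of wind. Soil and sediment are immobile. Wind direction is fixed
per run. Each region additionally vents to the open domain boundary the
part of its swept air flow not handed to a downwind neighbour — without
this, terminal downwind regions would accumulate without bound. The coupled
block system stays linear and uses the same exact propagator. The packaged
13-district layout is a stylised grid (synthetic geometry, not survey data)
that honours the districts' relative compass positions and land-use
contrasts; its inter-district flows and river partitioning are assumptions.
Because the multi-box mode uses full ventilation physics while the lumped
regional calibration deliberately uses a small effective exchange (below),
district-level absolute risks are much lower than the lumped model's and
should be read relatively, district against district.

## Packaged scenario and the reconstruction

The packaged "Nanjing default" parameter set is a **documented
reconstruction**, not a transcription: the only values taken as printed are
the 2002–2008 yearly emission rates (air transportation + industry; water
industry), the initial fugacities (10⁻¹¹, 10⁻¹⁰, 10⁻¹¹, 10⁻¹⁰ Pa), the
inflow concentrations (10⁻¹¹ and 10⁻⁷ mol/m³ for air and water), the annual
mean temperature (15.4 °C) and precipitation (1000 mm). Geometry, phase
composition, transfer velocities, exposure factors and dose–response
factors were assembled from Mackay-typical values and standard
exposure-factor/slope-factor literature, then adjusted in a single
calibration pass against the reported concentration levels (air 2.34 ng/m³
in 2002; water 0.025 µg/L and soil 16 ng/g in 2007; sediment 15.04 ng/g in
2002) and the reported sensitivity structure. Notable calibrated choices,
all marked `reconstructed` in the YAML:

* **Air exchange**: an effective cross-section of 1.54×10⁴ m² (G_a ≈ 4×10⁹
  m³/day at 3 m/s). Full physical ventilation of the region would be
  ~10¹³ m³/day and would make the background inflow dominate the air
  compartment, which is irreconcilable with the reported ~93% sensitivity
  of total risk to the local air emission rate; the small effective
  exchange follows the sensitivity structure.
* **Surface soil layer**: 5 mm deep over the non-water land area. The
  yearly emission totals cannot supply a conventional 0.1–0.2 m soil
  compartment with double-digit ng/g concentrations under any capture
  efficiency; a thin active surface layer is the only mass-consistent
  reading.
* **Air half-life 90 days** (aerosol-bound chemical shielded from OH and
  photolysis), **soil half-life 4 years** (aged residues), water and
  sediment half-lives from the standard reactivity classes.
* **Deposition**: dry deposition velocity 5 m/day (accumulation-mode
  aerosol), scavenging ratio 10⁴, gas washout off, net sediment deposition
  velocity 0.015 m/day applied to the suspended-solids phase (net of
  resuspension), suspended-solids volume fraction 10⁻⁴ (a sediment-laden
  river).
* **Exposure/dose–response**: 60 kg body weight, 20 g/day non-fish lipid
  intake, 25 g/day fish at 5% lipid, oral slope factor 7.3 (mg/kg/day)⁻¹,
  inhalation unit risk 1.1×10⁻⁶ (ng/m³)⁻¹, tap-water unit risk 2.1×10⁻⁷
  (µg/L)⁻¹, dermal permeability 3×10⁻⁵ m/day.

### Known limitation: absolute risk scale

The reconstruction reproduces the reported concentration levels and the
sensitivity structure, but **not** the reported absolute risks (~10⁻⁶) or
the reported fugacity range (10⁻¹⁴–10⁻¹³ Pa). These are mutually
inconsistent: an air concentration of 2.34 ng/m³ at a fugacity of 10⁻¹³ Pa
would require a bulk air Z of ~40 mol m⁻³ Pa⁻¹, i.e. an aerosol volume
fraction around 10⁻⁷ (hundreds of g/m³ of particles), and similar
contradictions hold for water and sediment. With physically admissible Z
values, fugacities consistent with the reported concentrations are ~10⁻⁹
Pa, and the equilibrium lipid-partitioning food model then yields food
doses — and hence total risks — some four orders of magnitude above 10⁻⁶.
All risk *ratios* (pathway ordering food ≫ inhalation ≫ tap water ≈ dermal),
the sensitivity coefficients, and the concentration outputs are scale-free
or concentration-based and unaffected. Absolute risk outputs of the
packaged scenario should therefore be read as upper-bound screening values
driven by the conservative food model, not as calibrated population risks.

## Synthetic meteorology

The generator emulates the statistical structure the analysis needs, not
any observed year: temperature = 288.55 K annual mean − 10 K cosine
seasonal cycle + N(0, 2 K) noise; rain as Bernoulli(0.30) occurrence with
gamma(0.8) intensities scaled so the expected annual depth is 1000 mm; wind
speed lognormal (median 3 m/s, σ=0.4); direction drawn from
prevailing-direction weights (east/southeast-heavy May–October,
east/northeast-heavy otherwise). Leap days repeat the previous day so every
year sees the same statistical forcing. What it does **not** emulate:
serial correlation of weather (fronts, wet spells), diurnal cycles,
temperature–rain dependence, or inter-annual climate variability. Passing
tests therefore demonstrate correct model behaviour under realistic
marginal forcing distributions, not skill against observed meteorology.

## Numerical choices and degenerate inputs

Tolerances: steady-state/trajectory oracle agreement 1% at 20 time
constants; mass-balance audit threshold 0.1% (achieved ~10⁻¹⁴); negative
fugacity guard 10⁻¹⁵ Pa. Zero interface areas, zero film velocities, zero
rain, fully sealed soil (builtup = 1) and zero irrigation all degrade
gracefully to zero D values; zero `V·Z` raises. Division-sensitive
exposure parameters (body weight, lipid density) are validated strictly
positive. Ties in wind direction (exact crosswind, cos θ = 0) create no
link. The one-row-per-parameter sensitivity table keeps both perturbation
factors as columns and sorts by max |S̄|.

## Problem sizes

The packaged case study integrates 2557 daily steps (2002-01-01 through
2008-12-31, calendar leap days included) in well under a second; the
sensitivity table re-runs the full chain per parameter×factor; Monte Carlo
uses 5000 draws per group combination; the spatial example couples 13
districts (52 state variables) over one year. The test suite and the
acceptance script each complete in seconds on one CPU.
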