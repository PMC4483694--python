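# Packaged Nanjing regional parameter set.
#
# This is a documented reconstruction, not a transcription: the study that
# motivates the packaged scenario only prints the emission table, the initial
# fugacities, the inflow concentrations and a handful of climate facts.
# Everything else (geometry, phase composition, transfer velocities, exposure
# factors, dose-response factors) is assembled from standard multimedia-model
# practice and exposure-factor literature, then adjusted in a single
# documented calibration pass (see docs/methods.md).
#   provenance "printed"       -> value printed in the source study
#   provenance "reconstructed" -> assembled/calibrated value
environment:
  temperature_k: 288.55            # printed: 15.4 C annual mean
  compartments:
    air:
      volume_m3: 3.949e+12          # reconstructed: 6582 km2 x 600 m mixing height
      phase_fractions: {gas: 0.99999999998, aerosol: 2.0e-11}   # reconstructed (Mackay-typical aerosol load)
      solids_density_kg_m3: 1500.0
      organic_carbon_fraction: 0.0
    water:
      volume_m3: 3.5e+9             # reconstructed: 700 km2 x 5 m
      phase_fractions: {water: 0.999899, solids: 1.0e-4, biota: 1.0e-6}  # reconstructed; solids ~ Yangtze suspended load
      solids_density_kg_m3: 2400.0
      organic_carbon_fraction: 0.2
      biota_lipid_fraction: 0.05
    soil:
      volume_m3: 2.94e+7            # reconstructed: 5880 km2 x 5 mm active surface layer
      phase_fractions: {solids: 0.5, water: 0.2, air: 0.3}
      solids_density_kg_m3: 2400.0
      organic_carbon_fraction: 0.02
      builtup_fraction: 0.15       # reconstructed: sealed urban surface share
    sediment:
      volume_m3: 2.1e+7             # reconstructed: 700 km2 x 3 cm active layer
      phase_fractions: {solids: 0.3, water: 0.7}
      solids_density_kg_m3: 2400.0
      organic_carbon_fraction: 0.05
  areas:
    air_water_m2: 7.0e+8
    air_soil_m2: 5.88e+9
    water_sediment_m2: 7.0e+8
  transport:                        # all reconstructed (Mackay-typical or calibrated)
    air_water_mtc_air_side_m_day: 72.0
    air_water_mtc_water_side_m_day: 0.72
    air_soil_mtc_air_side_m_day: 24.0
    soil_air_diffusion_mtc_m_day: 1.0e-6
    dry_deposition_velocity_m_day: 5.0
    scavenging_ratio: 1.0e+4
    suspended_settling_velocity_m_day: 0.015   # net deposition velocity (gross
                                               # settling minus immediate resuspension)
    sediment_resuspension_velocity_m_day: 1.0e-6
    sediment_water_diffusion_mtc_m_day: 2.4e-5
    soil_water_runoff_m_day: 3.0e-6
    soil_solids_runoff_m_day: 5.0e-8
    irrigation_flow_m3_day: 2.7e+6
    air_exchange_cross_section_m2: 1.543e+4
    river_flow_m3_day: 2.6e+9
    wet_gas_washout: false          # reconstructed: kinetically limited for a
                                    # particle-bound chemical; switchable
    wet_particle_scavenging: true

initial_fugacity_pa: [1.0e-11, 1.0e-10, 1.0e-11, 1.0e-10]   # printed (air, water, soil, sediment)
inflow_concentration_mol_m3: {air: 1.0e-11, water: 1.0e-7}  # printed

emissions_mol_day:                  # printed emission table, 2002-2008
  2002: {air_transportation: 0.43, air_industry: 0.89, water_industry: 0.17}
  2003: {air_transportation: 0.50, air_industry: 1.04, water_industry: 0.16}
  2004: {air_transportation: 0.51, air_industry: 1.06, water_industry: 0.15}
  2005: {air_transportation: 0.59, air_industry: 1.22, water_industry: 0.15}
  2006: {air_transportation: 0.62, air_industry: 1.28, water_industry: 0.14}
  2007: {air_transportation: 0.64, air_industry: 1.32, water_industry: 0.13}
  2008: {air_transportation: 0.69, air_industry: 1.43, water_industry: 0.12}

meteorology:                        # generator settings; climate facts printed
  annual_mean_temperature_k: 288.55 # printed (15.4 C)
  seasonal_amplitude_k: 10.0        # reconstructed
  temperature_noise_k: 2.0          # reconstructed
  coldest_day_of_year: 15           # reconstructed
  annual_rain_mm: 1000.0            # printed
  rain_frequency: 0.30              # reconstructed
  rain_gamma_shape: 0.8             # reconstructed
  wind_speed_lognormal_mean_m_s: 3.0    # reconstructed
  wind_speed_lognormal_sigma: 0.4       # reconstructed
  # prevailing directions: east/southeast in summer, east/northeast in winter (printed, qualitative)
  direction_weights_summer: {E: 0.35, SE: 0.35, S: 0.10, NE: 0.05, N: 0.05, SW: 0.05, W: 0.025, NW: 0.025}
  direction_weights_winter: {E: 0.35, NE: 0.35, N: 0.10, SE: 0.05, S: 0.05, NW: 0.05, W: 0.025, SW: 0.025}

exposure_profile:                   # reconstructed (exposure-factor literature)
  lipid_intake_g_day: 20.0
  fish_intake_g_day: 25.0
  fish_lipid_fraction: 0.05
  lipid_density_g_m3: 9.0e+5
  body_weight_kg: 60.0
  dermal_surface_area_m2: 1.8
  dermal_permeability_m_day: 3.0e-5
  shower_time_fraction: 0.0083      # ~12 min/day
  food_origin_fraction: 1.0

dose_response:                      # reconstructed (standard BaP values)
  sf_food: 7.3                      # per mg/(kg day), oral slope factor
  sf_dermal: 7.3                    # per mg/(kg day)
  ur_water: 2.1e-7                  # per ug/L
  ur_inhalation: 1.1e-6             # per ng/m3

distributions:                      # Monte Carlo parameter uncertainty
  - {path: concentration.air,   family: triangular, a: 0.5, m: 1.0, b: 1.5, group: 1, relative: true}
  - {path: concentration.water, family: triangular, a: 0.5, m: 1.0, b: 1.5, group: 1, relative: true}
  - {path: exposure.body_weight_kg, family: triangular, a: 45.0, m: 60.0, b: 75.0, group: 2}
  - {path: dose_response.sf_food,   family: triangular, a: 3.65, m: 7.3, b: 10.95, group: 3}
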