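# Benzo[a]pyrene physicochemical record.
# provenance: "handbook" = standard literature value (Mackay-type compilations);
# "reconstructed" = not printed in any primary source used here, chosen and
# documented in docs/methods.md (single calibration pass against the packaged
# Nanjing scenario's reported concentration levels).
name: benzo[a]pyrene
molar_mass_g_mol: 252.3                 # handbook
vapor_pressure_pa: 7.0e-7               # handbook, solid at 25 C
solubility_mol_m3: 1.506e-5             # handbook (0.0038 g/m3)
# henry_pa_m3_mol omitted -> derived as vapor_pressure / solubility (0.0465)
log_kow: 6.04                           # handbook
# koc_m3_kg omitted -> Karickhoff rule 0.41 * Kow (L/kg)
melting_point_k: 452.0                  # handbook
reference_temperature_k: 298.15
half_life_days:
  air: 90.0                             # reconstructed: predominantly
                                        # aerosol-bound, shielded from OH/photolysis
  water: 71.0                           # handbook (1700 h reactivity class)
  soil: 1460.0                          # reconstructed: within the 2-8 y
                                        # literature range for aged soil residues
  sediment: 2292.0                      # handbook (55000 h class); burial folded in
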