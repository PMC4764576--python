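{
  "schema_version": 1,
  "_comment": "Illustrative (non-canonical) capsaicin-extended parameter set: the vanilloid promotes opening strongly (c_L >> 1) with weak coupling to the temperature-sensor steps, so saturating capsaicin pins P_o near its maximum across the experimental temperature window.",
  "L": 0.005,
  "J1": {"dH0_kcal_per_mol": 30.0, "dS0_kcal_per_mol_K": 0.1079136690647482},
  "J2": {"dH0_kcal_per_mol": 80.0, "dS0_kcal_per_mol_K": 0.2515723270440251},
  "D": 50.0,
  "E": 1000.0,
  "K1_prime_per_M": 142.85714285714286,
  "F": 0.12,
  "G": 0.01,
  "H": 1.0,
  "K2_prime_per_M": 10000000.0,
  "caps_couplings": {"c_L": 2000.0, "c_J1": 1.0, "c_J2": 1.0, "c_Na": 1.0},
  "coop_exponent": 1.5
}
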